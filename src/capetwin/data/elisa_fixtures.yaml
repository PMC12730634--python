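# Control-normalised ELISA fold-change means used to generate synthetic
# plate fixtures (marker level relative to the untreated control = 1).
#
# The entries listed under `printed` are the anchors reported with the
# assays (CA 72-4 at 48 h / 100 uM = 2.8x; decorin 24 h plateau at
# 50-200 uM = 1.8x; decorin 48 h / 100 uM = 3.5x).  All other values are
# SYNTHETIC: monotone interpolations consistent with the described
# qualitative dose-response shapes (near-control CA 72-4 at 24 h up to
# 50 uM; decorin rising from 10 uM at 48 h; mild decline at 200 uM).

ca72_4:
  24:
    means: {0: 1.0, 10: 1.0, 25: 1.02, 50: 1.05, 100: 1.4, 200: 1.3}
    printed: []
  48:
    means: {0: 1.0, 10: 1.1, 25: 1.3, 50: 1.8, 100: 2.8, 200: 2.3}
    printed: [100]

decorin:
  24:
    means: {0: 1.0, 10: 1.05, 25: 1.4, 50: 1.8, 100: 1.8, 200: 1.8}
    printed: [50, 100, 200]
  48:
    means: {0: 1.0, 10: 1.4, 25: 2.0, 50: 2.7, 100: 3.5, 200: 3.2}
    printed: [100]
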