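# Default sex-marker panels per microarray platform, built from the platform
# probe annotations (gene -> probeset ids).  Directions are implied by gene:
# XIST is female-specific; KDM5D and RPS4Y1 are Y-linked male-specific.
#
# Probesets listed here are the raw platform representation; quality filtering
# (filter_probesets) decides which survive on a given dataset.
GPL96:
  XIST: [214218_s_at, 221728_x_at]
  KDM5D: [206700_s_at]
  RPS4Y1: [201909_at]
GPL570:
  XIST:
    - 214218_s_at
    - 221728_x_at
    - 224588_at
    - 224589_at
    - 224590_at
    - 227671_at
    - 243712_at
  KDM5D: [206700_s_at]
  RPS4Y1: [201909_at]
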