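# Default specifications for the 26 variant-effect predictors benchmarked on the
# Kv-family broad dataset. `orientation: higher` means larger scores are more
# damaging; `lower` means smaller scores are more damaging (SIFT-like tools).
# `default_threshold` is the published family-tuned deleterious cutoff; binarize
# uses a strict inequality in the tool's orientation. Categorical tools carry a
# category -> {damaging, tolerated} map used instead of the numeric rule.
tools:
  - {name: AlphaMissense, orientation: higher, default_threshold: 0.5}
  - {name: ClinPred, orientation: higher, default_threshold: 0.8}
  - {name: DEOGEN2, orientation: higher, default_threshold: 0.5}
  - {name: MetaRNN, orientation: higher, default_threshold: 0.6}
  - {name: VARITYR, orientation: higher, default_threshold: 0.5}
  - {name: REVEL, orientation: higher, default_threshold: 0.45}
  - {name: VARITYER, orientation: higher, default_threshold: 0.5}
  - {name: VEST4, orientation: higher, default_threshold: 0.5}
  - {name: LISTS2, orientation: higher, default_threshold: 0.85}
  - {name: PROVEAN, orientation: lower, default_threshold: -1.5}
  - {name: SIFT4G, orientation: lower, default_threshold: 0.05}
  - {name: CADD, orientation: higher, default_threshold: 3}
  - {name: MetaLR, orientation: higher, default_threshold: 0.4}
  - {name: MPC, orientation: higher, default_threshold: 2}
  - name: MutationAssessor
    orientation: higher
    default_threshold: 1.7
    categorical_map: {H: damaging, M: damaging, L: tolerated, N: tolerated}
  - {name: MVP, orientation: higher, default_threshold: 0.75}
  - name: PPH_HVAR
    orientation: higher
    default_threshold: 0.45
    categorical_map:
      probably damaging: damaging
      possibly damaging: damaging
      benign: tolerated
  - {name: SIFT, orientation: lower, default_threshold: 0.0045}
  - {name: MetaSVM, orientation: higher, default_threshold: 0}
  - name: PPH_HDIV
    orientation: higher
    default_threshold: 0.45
    categorical_map:
      probably damaging: damaging
      possibly damaging: damaging
      benign: tolerated
  - {name: MCap, orientation: higher, default_threshold: 0.05}
  - {name: PrimateAI, orientation: higher, default_threshold: 0.6}
  - {name: DANN, orientation: higher, default_threshold: 0.5}
  - {name: GenoCanyon, orientation: higher, default_threshold: 0.7}
  - {name: FATHMM, orientation: lower, default_threshold: -1}
  - {name: ESM1b, orientation: lower, default_threshold: -3}
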