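# Demo configuration: three synthetic tumor-vs-wild-type comparisons
# (one commercial-like and two patient-derived-like cell lines), each
# with its own spiked kinases, aggregated over four pipelines.
seed: 11

thresholds:
  r2_min: 0.90
  fc_up: 1.30
  fc_down: 0.70
  intensity_floor: 0.0

krsa:
  iterations: 3000
  z_threshold: 2.0

aggregation:
  total_pipelines: 4
  top_k: 10
  groups:
    patient_derived: [SIM-PDCL-A, SIM-PDCL-B]
    all: [SIM-PANC, SIM-PDCL-A, SIM-PDCL-B]

simulate:
  n_kinases: 60
  noise_sd: 10.0
  nonlinear_fraction: 0.10
  undetectable_fraction: 0.05
  n_replicates: 3
  contexts:
    SIM-PANC:
      spiked: [[KIN001, 1.5], [KIN010, -1.0]]
    SIM-PDCL-A:
      spiked: [[KIN001, 1.2], [KIN020, 1.5]]
    SIM-PDCL-B:
      spiked: [[KIN020, 1.5]]
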