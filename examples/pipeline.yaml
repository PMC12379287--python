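# Demo run config for `gvscan run examples/pipeline.yaml --seed 7 --out run/`
stages:
  - name: phantom-titration
    params:
      y0: 1.2
      ymax: 60.0
      half_max_conc_um: 50.0
      hill_n: 1.6
      concentrations_um: [0, 5, 10, 25, 50, 100, 250, 1000]
      n_reps: 4
      noise_cv: 0.1
  - name: invivo-scan
    params:
      lateral_steps: 3
      longitudinal_steps: 10
      image_shape: [24, 16]
      gv_amplitude: 3.0
      noise_sd: 0.05
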