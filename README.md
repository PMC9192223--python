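# mimodes

Motor-imagery EEG decoding built around empirical mode decomposition:

* **EMD** with cubic-spline extrema envelopes and the SD sifting-stop
  criterion (threshold in the 0.2–0.3 range, default 0.25);
* **EEMD** — noise-assisted ensemble averaging that cancels added white
  noise and alleviates mode mixing;
* **Sub-band preprocessing** — wavelet denoising, a periodized level-4
  wavelet-packet split (db4, self-contained filter bank), EMD of selected
  nodes (default frequency-ordered nodes (4,1) and (4,3)), and retention of
  the IMFs most correlated with each node signal (the first two in
  practice), stacked into an 8 × 2000 per-trial matrix at the defaults;
* **CSP** spatial filtering with log-variance features, plus a weighted
  pairwise scatter matrix and per-IMF energy profiles;
* **Classifier** — a regularized discriminant producing per-trial decision
  values, kernel-density decision curves with overlap-area reporting, and a
  decision threshold selected so the relaxed-state false-positive rate does
  not exceed a bound (default 10%);
* **Synthetic data** — seeded generators for decomposition test signals and
  two-class motor-imagery EEG with contralateral mu/beta ERD over 1/f
  background noise.

## Command line

```sh
# generate a labeled synthetic dataset (CSV per trial + labels + manifest)
mimodes simulate --out data/ --seed 7 --n-trials 50 --erd-depth 0.5

# decompose a single-channel CSV into IMFs (optionally per WPT sub-band)
mimodes decompose --input channel.csv --fs 250 --out dec/ --method emd
mimodes decompose --input channel.csv --fs 250 --out dec/ --method eemd \
    --ensemble-size 100 --noise-std 0.2 --seed 1 --subband

# train the decoder and cap the relaxed-state FPR at 10%
mimodes train --data data/ --model model.json --report report.json --fpr-max 0.10

# score new trials
mimodes run --data data/ --model model.json --out decisions.csv
```

A YAML config file (`--config`) can set any stage's parameters under the
sections `emd`, `subband` (`wavelet_name`, `wpt_level`, `nodes`,
`imfs_kept`, `node_order`) and `simulate`; command-line flags take
precedence. Every run logs its config hash and seed to stderr.

Python API: see `mimodes.emd`, `mimodes.eemd`, `mimodes.subband`,
`mimodes.features`, `mimodes.classifier`, `mimodes.simulate`,
`mimodes.pipeline` (`train_decoder` / `decode_trials`), `mimodes.io`.

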