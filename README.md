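# rootmedia

Surrogate modeling and optimization of macronutrient ions for *in vitro*
rooting media of the almond × peach hybrid rootstock G×N15 (Garnem).

Micropropagated *Prunus* shoots root on a gel medium whose macronutrient
composition strongly affects success. An experiment varied four salts —
KNO₃, NH₄NO₃, Ca(NO₃)₂·4H₂O and CaCl₂·2H₂O — over 36 factorial media and
recorded five rooting responses per treatment (mean ± SE over 6 replicates):
root number (RN), root length (RL, cm), rooting percentage (R%, as a
proportion), and fresh/dry root weight (FW/DW, g). This package rebuilds the
full modeling chain over those printed tables:

1. **Stoichiometry** — salt masses (mg/L) → ion concentrations
   (NO₃⁻, NH₄⁺, K⁺, Ca²⁺, Cl⁻ in mM), cross-checked against the published
   ion table to 0.02 mM.
2. **Replicate synthesis** — the 36 means ± SE are expanded into the
   216-row replicate dataset the models were fitted to
   (per-replicate SD = SE·√6, clamped to each response's physical domain),
   min–max normalized to [−1, 1] and split 130 train / 86 test.
3. **Surrogate networks** — one 5–8–1 feed-forward network per response:
   hidden unit *i* computes tansig(Σₙ wₙᵢ xₙ + bᵢ) with
   tansig(n) = 2/(1+e^(−2n)) − 1 ≡ tanh(n), linear output; trained by
   Levenberg–Marquardt with analytic Jacobian until the per-sample training
   MSE reaches 0.01 or 800 epochs. Fit is reported as R², RMSE and signed
   mean bias error (MBE).
4. **Sensitivity** — per-ion variable sensitivity error (VSE: model RMSE
   with that input unavailable) and ratio (VSR = VSE / full-model RMSE);
   ions ranked by descending VSR.
5. **GA optimization** — a real-coded genetic algorithm (population 50,
   500 generations, roulette-wheel selection, arithmetic crossover at 0.85,
   Gaussian mutation at 0.1, one elite) maximizes each trained surrogate
   over the ion box spanned by the 36 media.

## Worked example

```bash
python analysis/01_verify_stoichiometry.py
python analysis/03_train_surrogates.py
```

prints (seed 0):

```
per_salt      :  0 entries beyond 0.02 mM (max |diff| 0.0098 mM)
stoichiometric: 18 entries beyond 0.02 mM (max |diff| 2.9856 mM)
                flagged media 19–36, ions ['cl']

response  train_r2  test_r2  published_test_r2  test_rmse  test_mbe  epochs   stop_reason
      RN     0.925    0.838              0.880      0.928    -0.019      12      mse_goal
      RL     0.933    0.743              0.880      0.175    -0.024      26 damping_limit
      R%     0.981    0.942              0.980      0.045    -0.005       4      mse_goal
      FW     0.943    0.874              0.940      0.034    -0.004       8      mse_goal
      DW     0.930    0.750              0.870      0.023    -0.006      44 damping_limit
```

The first block confirms that the published ion table counts one Cl⁻ per
CaCl₂·2H₂O (the `per_salt` convention reproduces it exactly; doubling Cl⁻,
as strict stoichiometry would, flags exactly the 18 chloride media). The
second block shows each surrogate's fit on its held-out 86-row partition
next to the published value: held-out R² is limited by the replicate noise
implied by the printed SEs, so responses with small between-treatment spread
(RL, DW) sit below their published values — see `docs/methods.md` for the
noise-ceiling analysis. The remaining drivers
(`analysis/02_simulate_replicates.py`, `04_rank_ion_importance.py`,
`05_optimize_media.py`) write the replicate datasets, the VSR/rank table
(K⁺ first, NO₃⁻ last for the well-resolved responses) and the GA-optimal
media with convergence trajectories, all under `results/`.

The same stages are scriptable via the `rootmedia` CLI
(`ions`, `verify`, `simulate`, `train`, `sens`, `optimize`, `reproduce`) or
the library API (`rootmedia.pipeline.reproduce`).

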