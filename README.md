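# tinnet

Symptom-network analysis of depression–anxiety comorbidity from ordinal
questionnaire data.

Clinical questionnaires such as the PHQ-9 (nine depression items) and
GAD-7 (seven anxiety items) score each symptom 0–3.  Network psychometrics
treats comorbidity not as two latent diseases but as a web of direct
symptom–symptom interactions: which symptoms are most central to the web,
and which *bridge* the two disorders.  `tinnet` implements that analysis
end to end, for researchers working with item-level screening data:

* ordinal instrument model — validation (complete-case), total scores,
  severity bands, Cronbach's α;
* Spearman rank-correlation matrix (average-rank ties, PSD repair);
* Gaussian graphical model via graphical lasso over a 100-step penalty
  path with EBIC selection (γ = 0.5): edge weights are regularised
  partial correlations `w_ij = −K_ij / √(K_ii K_jj)`;
* centrality: expected influence `EI_i = Σ_j w_ij`, bridge expected
  influence `BEI_i = Σ_{j ∉ comm(i)} w_ij`, bridge symptoms by the blind
  80th-percentile rule, and the BFS flow decomposition around a focal
  symptom (suicidal ideation by default);
* predictability: nodewise in-sample R² from network neighbours;
* stability: nonparametric bootstrap CIs for edges, case-dropping
  correlation-stability (CS) coefficients for centralities, and pairwise
  bootstrapped difference tests (nboots = 2000, α = 0.05 by default);
* a synthetic-cohort generator (latent Gaussian with known sparse
  precision matrix, discretised to 0–3 by calibrated thresholds) so that
  every stage is testable by parameter recovery against ground truth.

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

Generate the default synthetic cohort (566 subjects, 9 + 7 items, three
planted bridge symptoms A7/D6/D7) and run the analysis steps:

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_score_questionnaires.py
python analysis/03_estimate_network.py
python analysis/04_centrality_predictability.py
python analysis/05_stability.py
python analysis/06_recovery_benchmark.py --n-seeds 5
```

The scoring step prints, for this seed:

```
validated 566/566 subjects (0 rejected)
depression: mean total 6.70, alpha = 0.77
anxiety: mean total 5.57, alpha = 0.60
```

i.e. nobody was dropped by complete-case validation, and both scales show
the internal consistency implied by the generator's latent network.
Network estimation reports

```
selected lambda 0.0996: 43/120 edges (36% density)
strongest edges:
  A4--A7: +0.28
  D4--D5: +0.27
  A3--A7: +0.24
  ...
```

— of the 120 possible edges among 16 symptoms, 43 survive EBIC-glasso
selection at this seed, and the strongest partial correlations are all
positive.
The centrality step then flags the bridge symptoms and predictability:

```
highest expected influence: D8, D1, D5
bridge symptoms (>= 80th pct of BEI): D6, D7, A2, A7
mean predictability: 28%
flow around D9: 5 direct, 9 indirect; strongest direct: D2 (+0.16), D8 (+0.16)
```

All three planted bridges (A7, D6, D7) are recovered — the
80th-percentile rule on 16 nodes admits four, so one extra symptom (A2)
is flagged too.  The stability step reports percentile CIs, the fraction
of significantly differing pairs, and the CS coefficients:

```
significant pairwise differences: EI 63%, BEI 30%
CS(expected_influence) = 0.75
CS(bridge_expected_influence) = 0.55
```

`CS = 0.75` means the EI ranking still correlates ≥ 0.7 with the
full-sample ranking when three quarters of subjects are dropped (≥ 0.5 is
conventionally "good" stability).  Finally the recovery benchmark scores
estimates against the generator's truth at n = 5000 (five seeds): strong
true edges (|w| ≥ 0.1) are recovered always (sensitivity 1.0, weight RMSE
0.037, planted-bridge hit rate 1.0), while edge-pattern specificity is
limited to ~0.46 by ordinal discretisation (see `docs/methods.md`, Known
limitations).

The same pipeline runs on real data: any CSV with a `subject` column and
`D1..D9`/`A1..A7` item columns (or custom `Instrument` definitions), via
the library (`tinnet.run_pipeline`) or the CLI
(`tinnet run-all --input cohort.csv --out results/ --seed 0`).

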