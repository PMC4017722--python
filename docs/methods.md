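# Methods

## Model and procedure

The package analyses `m` scoring systems against one experimental activity
table. A scoring system is nothing more than a map from compound id to an
estimated IC50 in nM; where those estimates come from (pharmacophore
hypotheses, docking rescoring, ML regressors) is outside the package — the
analysis consumes prediction tables.

The pipeline stages are:

1. **Split validation.** A training/testing split is checked against four
   rules: disjoint ids (complete, unambiguous records), at least 16 training
   compounds, the training set contains the most- and least-potent compound
   overall, and the training activities span at least 4 orders of magnitude.
   Violations are reported as flags, not exceptions, because a user may
   legitimately analyse a split that fails them.
2. **Individual evaluation.** Pearson `r` between experimental and predicted
   activities, by default on log10-transformed IC50. Correlations are
   exposed with full precision and rounded to 3 decimals in reports.
3. **System selection.** Systems with `r < drop_fraction · max(r)` are
   dropped before enumeration (default `drop_fraction = 0.5`). This
   operationalizes "drop systems performing far below the rest": on the
   bundled training data (0.955, 0.840, 0.238) it removes exactly the third
   system. The threshold is a design choice, configurable, and reported.
4. **Diversity profiles.** For each pair of systems, the per-compound
   absolute difference of (log10) scores, its descending rearrangement
   `f(j)`, and the aggregate (the sum, equivalently the area under the
   rank/score graph). The aggregate is the scalar used to rank pairs; the
   underlying graphs are exportable as two-column CSVs.
5. **Exhaustive fusion.** All `2^m − 1` non-empty subsets are combined and
   correlated with experiment; the leaderboard is sorted by `r_test`
   descending with deterministic tie-breaks (smaller subset first, then
   lexicographic member labels).
6. **Screening triage.** Strict inequalities on estimated IC50 (below) and
   docking interaction energy (above a redocked-reference value supplied by
   the user), plus top-k reporting by energy or potency.

## Key conventions and why

* **Log10 activity scale.** Activities span five orders of magnitude, so a
  raw-scale Pearson is dominated by the few least-potent compounds. On the
  bundled data the log10 convention reproduces the published per-system
  correlations to 3 decimals; the raw scale is retained as an option and
  does not (0.908 vs 0.955 for the best training system).
* **Score combination = mean of log10 activities** (geometric mean of
  IC50s), the natural unweighted average in the space where the evaluation
  happens. Arithmetic averaging of raw nM values is available as
  `mean_raw`. Rank combination, voting, and weighted schemes are
  deliberately not implemented.
* **Per-compound diversity.** The diversity score is defined per inhibitor
  and then sorted across the whole set; the sum over inhibitors is exposed
  separately as the profile aggregate. Only this reading makes "sort the
  diversity scores into descending order" meaningful.
* **Strict filter inequalities** (`<` potency, `>` energy). On the bundled
  screening table the choice is inert (no record sits on a boundary), but it
  is applied uniformly.
* **Determinism.** Every sort has an explicit tie-break (compound id or
  system label, lexicographic). Pipeline runs are reconstructible from their
  logged configuration; fixture files carry sha256 checksums verified at
  load time.

## Synthetic-data generator

`simulate_study` draws true log10 activities **uniformly** over
`[base, base + span_orders]` — uniform rather than log-normal because the
split rules constrain the span of orders of magnitude, and a uniform draw
makes the span exact by construction. System `k` predicts
`truth + bias_k + eps_k` with `(eps_1…eps_m)` jointly Gaussian
(per-system SDs `noise_sd`, correlation matrix `noise_corr`), back-
transformed to nM. A single `numpy.random.Generator` seeded from one integer
drives all draws, so identical configs give identical tables.

Dialling `noise_sd` sets individual accuracy
(`r ≈ σ_t/√(σ_t² + σ²)` with `σ_t² = span²/12`); dialling `noise_corr` sets
diversity: independent noise gives maximally diverse systems whose fusion
halves the noise variance, perfectly correlated noise gives clones whose
fusion is a no-op. The tests verify exactly this phase behaviour, plus
recovery of `noise_sd` and `bias` from the generated tables.

What the generator does **not** emulate: heteroscedastic or heavy-tailed
prediction errors, systematic non-linearity (e.g. range compression at the
potent end), censored activity values ("> 10 µM"), structural-analogue
clustering, or any relationship between docking energy and potency
(`simulate_screening` draws the two independently). Passing tests therefore
demonstrate correctness of the machinery and its expected behaviour under
the stated noise model, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

The bundled study tables are small (25/133/21 rows; 63 combinations), so all
fixture-derived quantities are exact desk-scale computations. Monte-Carlo
properties use 200 replicates of 150–300 test compounds — enough to resolve
the fusion gain (~0.03–0.04 in `r`) against replicate noise — and
parameter-recovery checks use n = 10,000 with 3-standard-error bands from
the chi-distribution SE of a Gaussian SD estimate. Degenerate inputs
(zero-variance vectors, fewer than 2 points, non-positive activities,
non-PSD noise correlations) raise typed errors rather than propagating NaNs.

## Known limitations

* The fusion correlation recomputed from the printed 1-decimal estimates of
  the bundled testing table is 0.814 for the best pair; published
  intermediate rounding can shift such values by a few thousandths.
* Aggregate diversity is a single scalar summary of the rank/score graph;
  two graphs with equal area but different shape are not distinguished by
  the pair-ranking heuristic (the full graphs are exported for inspection).
* `select_systems` uses a relative threshold on `r`; it has no notion of
  statistical uncertainty in the correlations.
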