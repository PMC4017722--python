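# qsarfusion

Combinatorial fusion analysis for activity-prediction systems in early drug
discovery: given experimental IC50 values for a set of inhibitors and the
estimates of several QSAR/pharmacophore scoring systems, the package measures
how well and how *differently* the systems predict, exhaustively evaluates
every score combination, and applies the downstream virtual-screening triage
filters (potency and docking-energy cutoffs).

The bundled study data are checkpoint kinase 2 (Chk2) inhibitors: a training
set of 25 compounds with three pharmacophore-hypothesis generators, a testing
set of 133 compounds with six prediction systems (BB, BF, BC, FB, FF, FC —
train-algorithm x test-algorithm), and 21 post-docking screening candidates.

## The method

Each prediction system `A` is a score function `s_A` assigning every
inhibitor `p_i` an estimated IC50. Systems are judged by the Pearson
correlation `r` between experimental and estimated activities on the log10
scale (`r_train` / `r_test`). For a pair of systems `(A, B)` the per-inhibitor
**diversity score** is

    d_i(A, B) = | s_A(p_i) − s_B(p_i) |      (log10 activities),

and sorting the `d_i` into descending order gives the **diversity rank/score
function** `f_(A,B)(j)`, `j = 1…t` — its plot is the diversity rank/score
graph, and its sum is the scalar diversity of the pair. With `m` systems
there are `2^m − 1` non-empty subsets; each subset is fused by **score
combination** — the unweighted mean of the members' log10 activities, i.e.
the geometric mean of their IC50 estimates — and ranked by its `r_test`.
Fusion is expected to help only when the members each perform relatively
well *and* are diverse; both heuristics (drop systems far below the best
`r`; prefer pairs with large aggregate diversity) are implemented and
auditable.

Screening triage keeps candidates with estimated IC50 strictly below a
potency cutoff and docking interaction energy strictly above a redocked
reference value, then reports the top-k by energy.

## Worked example

```python
from qsarfusion import CombinatorialFusion, load_fixture

table, systems = load_fixture("table2")     # 133 inhibitors, 6 systems
results = CombinatorialFusion(table, systems).fit()
print(results.summary())
```

prints

```
Combinatorial Fusion Results
============================================================
Inhibitors (t):        133
Systems (m):           6
Selected for fusion:   BB, BF, BC, FB, FF, FC
Scale:                 log10
Combination rule:      mean_log
Combinations scored:   63
Pairwise profiles:     15

Individual systems
------------------------------------------------------------
system                   n         r
BB                     133     0.810
BF                     133     0.771
BC                     133     0.783
FB                     133     0.710
FF                     133     0.728
FC                     133     0.714

Top 10 combinations
------------------------------------------------------------
members                      size    r_test
BB+BC+FF                        3     0.819
BB+BC+FB                        3     0.814
BB+FF                           2     0.814
...
```

The individual `r_test` values are the six systems' correlations with
experiment; `BB+FF` is the best of the 15 pairwise fusions — combining the
two diverse, well-performing systems beats either alone (0.810 / 0.728).
The screening stage:

```python
from qsarfusion import FilterSpec, filter_screening, load_fixture, top_k

records = load_fixture("table3")
len(filter_screening(records, FilterSpec(min_energy_kcal_mol=37.786)))  # 21
len(filter_screening(records, FilterSpec(min_energy_kcal_mol=50.0)))    # 11
top_k(records, 1, key="energy")[0].id                                   # 'NSC 136954'
```

The same pipeline is available from the shell (`qsarfusion run`,
`qsarfusion evaluate table2`, `qsarfusion fuse table2`,
`qsarfusion screen table3 --min-energy 50`, `qsarfusion simulate`, …); every
run writes CSV reports and a log of all parameters and input checksums.

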