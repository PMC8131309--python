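# dualsarm

SAR-matrix analog design with generative matrix expansion and dual-target
candidate prioritization.

## The problem

Medicinal chemistry data sets contain many overlapping analog series:
compounds sharing a core structure and differing by one substituent.  The
SAR matrix (SARM) data structure makes this organization explicit.  A
dual-step fragmentation scheme, adapted from matched-molecular-pair
analysis, first cuts every exocyclic single bond of every compound into a
*key* (core) and *value* (substituent); cores are then re-fragmented the
same way to find cores differing by a chemical change at a single site.
Each set of such structurally analogous cores spans one matrix: rows are
cores, columns are substituents, and every cell is a compound — either an
existing, measured one or a *virtual analog*, an unexplored core/substituent
combination that the matrix implies.

`dualsarm` implements this pipeline end to end for the dual-target
(polypharmacology) setting, where the goal is compounds active against two
pre-defined targets:

- **fragmentation / sarm_core** — canonicalization, single-cut
  fragmentation into indexed key/value tables, core grouping, and SARM
  construction with existing and virtual cells.
- **freewilson_qsar** — local potency prediction for virtual cells.  For a
  virtual cell (i, j), every *matrix neighborhood* of measured cells
  (i, l), (k, j), (k, l) yields the additive (Free-Wilson) estimate

      pot(i, j) ≈ pot(i, l) + pot(k, j) − pot(k, l),

  and the prediction is the mean over neighborhoods, with its spread.  A
  global least-squares additive fit (pot = μ + aᵢ + bⱼ, Σaᵢ = Σbⱼ = 0) is
  provided as the reference estimator.
- **generative** — three LSTM encoder-decoder fragment generators
  (scaffold, core-substructure, and substituent roles), pre-trained on a
  pooled fragment corpus from both target classes and fine-tuned on the
  fragments of known dual-target ligands.  Each generated fragment carries
  a log-likelihood score (sum of the decoder's per-token log-probabilities,
  always ≤ 0); fragments passing a score filter expand a SARM with new rows
  and columns, and each new virtual analog is scored by the sum of its
  fragments' scores.
- **dual_activity** — per-target gradient-boosted (LightGBM) potency models
  on Morgan fingerprints with an 80/20 split, and dual-target ranking of
  virtual candidates by their *worst* per-target predicted-potency rank, so
  only candidates predicted potent against both targets lead.
- **mgm** — Molecular Grid Maps: Tanimoto similarity, PCA/t-SNE embedding,
  exact assignment of compounds to a regular grid, similarity-weighted
  swap optimization, and an SVG renderer that draws each compound as a
  divided circle color-coded by the two targets' potencies.
- **synthetic_data** — a generator of combinatorial analog series with
  additive per-target potencies and known ground truth, so the whole
  pipeline is testable without any external data.

## Worked example

```python
from dualsarm.synthetic_data import SyntheticSpec, gen_analog_series
from dualsarm.fragmentation import build_compound_index, IndexTable
from dualsarm.sarm_core import fragment_cores, group_analogous_cores, build_sarms
from dualsarm.freewilson_qsar import predict_all_virtual

spec = SyntheticSpec(n_scaffolds=4, n_substituents=5, fill_fraction=0.5, seed=3)
ds = gen_analog_series(spec)                       # 10 compounds
index = build_compound_index(ds.compounds, potencies=ds.potency_records())
scaffolds = set(ds.truth.scaffolds)                # focus on the designed series
series = IndexTable(
    entries={k: v for k, v in index.entries.items() if k in scaffolds},
    compounds=index.compounds, potencies=index.potencies)
sarms = build_sarms(group_analogous_cores(fragment_cores(series)), series)
sarm = next(s for s in sarms if s.shape == (4, 5))
print(sarm.group.key2, sarm.shape, sarm.n_existing())
for p in predict_all_virtual(sarm, "A")[:3]:
    print(p.cell, round(p.predicted_pIC50, 2), p.n_neighborhoods)
```

prints

```
*c1ccc(*)cc1 (4, 5) 10
(0, 0) 6.35 3
(1, 1) 7.37 3
(1, 4) 9.52 1
```

The ten compounds form one SARM: four para-substituted benzene cores
(shared scaffold `*c1ccc(*)cc1`) by five substituents, with ten measured
cells and ten virtual analogs.  Each virtual cell gets a Free-Wilson
potency estimate from its measured matrix neighborhoods — e.g. cell (0, 0)
is predicted at pIC50 6.35 for target A from 3 neighborhoods.

The same flow is available from the shell:

```
dualsarm synth --seed 3 --out data/
dualsarm fragment --in data/compounds.csv --out index.json
dualsarm build --index index.json --out sarms/
dualsarm predict-fw --sarm sarms/sarm000.json --target A --out fw.csv
dualsarm run --seed 1 --out run/        # full pipeline incl. generators, MGM
```

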