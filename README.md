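# taucore

Structural and sequence analysis of the tau aggregation nucleation cores.

Tau protein aggregates into amyloid filaments in Alzheimer's disease and the
rarer tauopathies (Pick's disease, PSP, CBD, AGD, GGT and related
conditions).  Aggregation nucleates at two hexapeptides in the
microtubule-binding region: **VQIINK** (PHF6\*, residues 275–280, start of
repeat R2) and **VQIVYK** (PHF6, residues 306–311, start of repeat R3) on
2N4R numbering.  This package, aimed at structural biologists and protein
biochemists working on tau, implements the computational side of that
biology:

* **Contact analysis** of fibril protomer structures (PDB/mmCIF) under
  distance-only criteria — a hydrogen bond is a donor/acceptor-capable heavy
  atom pair at ≤ 3.3 Å, a hydrophobic contact an apolar carbon pair at
  ≤ 5.0 Å (both inclusive).  The k-d-tree engine is tested for exact
  equality against an exhaustive all-pairs oracle.
* **Strain classification**: a protofilament fold is *single-core* when only
  VQIVYK is ordered in its rigid core and *dual-core* when VQIINK is
  ordered too.  Across the eight published folds (AD 5O3L, CTE 6NWP, PiD
  6GX5, CBD 6TJO, AGD 7P6D, PSP 7P65, GGT 7P66, GPT 7P6A) this yields 3
  single-core and 5 dual-core strains.
* **Truncation-loss analysis**: the residue-pair interactions that disappear
  when a hexamer's last three residues (VYK or INK) are removed — the
  structural account of why the shared VQI trimer cannot nucleate on its
  own, and why VQIVYK ranks as the primary core (it anchors at least as
  many neighbourhood interactions as VQIINK in every dual-core fold).
* **Construct design**: the six brain isoforms (0–2 N-inserts × 3R/4R), the
  N1–N8 and C1–C5 truncation series over the domain boundaries, and the
  C6–C8 motif-extension constructs, with the *intact-hexamer rule*:
  a construct is predicted amyloidogenic iff it contains a full VQIVYK or
  VQIINK.
* **Kinetics calling**: logistic fits of ThT fluorescence time series and a
  binary competent/not-competent call, validated on simulated curves.
* **Synthetic fixtures**: structures with planted contacts at exactly known
  distances, mini fibril stacks, and simulated ThT curves, so the entire
  pipeline runs and is tested without any downloads.  The eight folds ship
  as synthetic stand-ins built from a profile table of modeled residue
  ranges and reported neighbour pairs; real depositions can be analysed
  with the same code (`taucore classify --fetch 5O3L ...` when online).

## Worked example

```python
from taucore.folds import build_all_fold_protomers
from taucore.reports import classify_protomers

table, details = classify_protomers(build_all_fold_protomers(seed=0))
print(table[["fold", "class", "n_pairs_PHF6", "n_pairs_PHF6star",
             "primary_core"]].to_string(index=False))
```

```
fold       class  n_pairs_PHF6  n_pairs_PHF6star primary_core
  AD single_core             2                 0         PHF6
 CTE single_core             2                 0         PHF6
 PiD single_core             1                 0         PHF6
 CBD   dual_core             4                 1         PHF6
 AGD   dual_core             3                 0         PHF6
 PSP   dual_core             5                 0         PHF6
 GGT   dual_core             5                 0         PHF6
 GPT   dual_core             5                 0         PHF6
```

Each row is one protofilament fold: its strain class, the number of
residue-pair interactions lost when the VYK (PHF6) or INK (PHF6\*) suffix is
truncated, and the resulting primary-core call.  In the AD fold, for
example, the lost PHF6 pairs are Tyr310–His374 and Tyr310–Leu376.

The same analyses are packaged as narrative scripts:

```
python analysis/01_design_constructs.py     # 22-construct panel + hexamer rule
python analysis/02_aggregation_kinetics.py  # ThT simulation + call statistics
python analysis/03_classify_strains.py      # eight-fold strain classification
python analysis/04_truncation_loss.py       # lost-interaction tables + ranking
```

each of which writes its tables under `results/`.  A `taucore` console
script exposes the same functionality (`classify`, `constructs`,
`simulate`, `contacts` subcommands).

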