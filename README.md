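# waterdock

Small-molecule docking with explicit interface water molecules.

Bridging waters — crystallographic waters hydrogen-bonded to both the
protein and the ligand — are part of the binding interface, yet most
docking pipelines strip them. `waterdock` implements a compact docking
protocol that samples a small set of explicit interface waters alongside
the ligand, in three variants:

* **standard** — no waters; rigid-body ligand placement and refinement.
* **protein-centric** — waters move independently near the binding site
  (≤4 Å translation, full reorientation) before the complex slides into
  contact.
* **ligand-centric** — waters ride the ligand as it translates and
  rotates, make small (≤1 Å) independent adjustments, and are reoriented
  to optimize their hydrogen bonding.

Around the docking core the package provides: loose/tight interface-water
classification, grid-based decoy-water placement at ligand polar atoms,
binding-site crowdedness, two-stage model selection and ranking with RMSD
success metrics, and exact binomial replication statistics for comparing
protocols across a benchmark. A deterministic synthetic pocket generator
makes the whole pipeline testable end to end without external structures.

The score function is a deliberately simplified Lennard-Jones +
hydrogen-bond stand-in, small enough that the test suite verifies it
against brute-force pair sums; see `docs/methods.md` for the full model,
parameters, and limitations.

## Worked example

Generate a synthetic pocket with one tight bridging water, classify its
waters, place decoy waters, and report site crowdedness:

```
$ waterdock fixtures pocket -o pocket.pdb
wrote pocket.pdb

$ waterdock select-waters pocket.pdb --mode tight -o waters
1 tight waters of 1

$ cat waters.tsv
index	n_protein_contacts	n_ligand_contacts	label
0	4	2	tight

$ waterdock decoy-waters pocket.pdb -o decoys.pdb
3 decoy waters

$ waterdock crowdedness pocket.pdb
n_polar_contacts	n_ligand_atoms	crowdedness
3	8	0.375
```

Dock the ligand with the ligand-centric water protocol (a small run for
illustration; real runs use `--nstruct 1000`):

```
$ waterdock dock pocket.pdb --protocol ligand-centric --nstruct 8 --seed 3 -o run_lc
top1_success=False rank_first_under=None

$ head -3 run_lc/ranked.tsv
model_id	total_score	interface_ligand	interface_water	ligand_rmsd	water_rmsd	rank
2	-13.634803	-10.263202	-1.868535	5.614265	5.115795	1
3	-18.181962	-9.261328	-2.842950	3.353092	8.250896	2
```

The run directory also contains per-model PDBs, the full `scores.tsv`,
and a `manifest.json` recording the seed and configuration hash; the same
seed reproduces the run byte for byte.

Exact replication statistics — the probability of at least 9 flips in 164
trials at a per-trial flip probability of 0.0136:

```
$ waterdock stats binom --n 164 --p 0.0136 --k 9
0.000455497
```

The same functionality is available as a Python API:

```python
from waterdock import make_toy_pocket, RunConfig, run_pipeline

structure, ligand, waters, native = make_toy_pocket()
cfg = RunConfig(protocol="ligand_centric", n_struct=100, output_dir="run")
summary = run_pipeline(cfg, native)
print(summary["metrics"])
```

## Layout

* `src/waterdock/structure.py` — PDB I/O, normalization, atom typing.
* `src/waterdock/waters.py` — interface-water classification, crowdedness.
* `src/waterdock/decoys.py` — grid-based decoy-water placement.
* `src/waterdock/scoring.py` — the simplified score function.
* `src/waterdock/lowres.py`, `highres.py` — the two docking stages.
* `src/waterdock/ranking.py`, `repstats.py` — selection, RMSD, statistics.
* `src/waterdock/fixtures.py` — synthetic pocket and ensemble generators.
* `src/waterdock/config.py`, `cli.py` — run configuration and CLI.
* `docs/methods.md` — model description, parameters, numerics, limits.
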