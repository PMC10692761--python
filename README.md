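# strucphy

Assemble and query non-redundant datasets for **structural phylogenetics**:
split protein structures into chains, cluster away sequence redundancy,
compare the cluster representatives with a secondary-structure-seeded
structural aligner, and export the resulting similarity neighbourhoods as
distance matrices and neighbour-joining trees.

Protein structure diverges far more slowly than sequence, so structure
comparison can relate proteins whose sequences have drifted past the point
of detectable similarity. That only works at scale if the inputs are
deduplicated (the same protein is often deposited hundreds of times) and if
the pairwise comparison yields a score that behaves like a similarity —
both of which this package automates.

## The model

* **Chains.** Every structure file is decomposed into per-chain records. A
  chain's *size* is the length of its deposited sequence record, not the
  number of resolved residues; chains shorter than 50 aa are dropped (too
  short to carry reliable structural signal).
* **Clusters.** Chains are greedily clustered at 90% semi-global sequence
  identity (UCLUST-style, longest-first, first-hit); each cluster is
  represented by its centroid. Members whose size deviates from the cluster
  median by more than one standard deviation are flagged low-confidence.
* **Vetting.** Each centroid must pass a structural self-check (at least
  one detectable secondary-structure element and a perfect self-alignment).
  Failing centroids are replaced by the largest passing member; clusters
  with no passing member (e.g. coil-only fragments) are removed.
* **Comparison.** Centroid pairs are aligned with a Cα-only structural
  aligner: secondary-structure elements (P-SEA-style geometric assignment)
  seed rigid superpositions, which are refined by iterated dynamic
  programming + Kabsch fitting. Quality is summarised by the **Qscore**

  ```
  Q = N_align² / ((1 + (RMSD/R0)²) · N1 · N2),      R0 = 3 Å
  ```

  which is 1 for identical structures and near 0 for unrelated ones. Pairs
  with no detectable structural (or sequence) similarity carry the sentinel
  −1. Sequence statistics (BLOSUM62 local alignment, bit score, E-value)
  are tabulated alongside.
* **Export.** A query chain's neighbourhood is the set of centroids with
  Qscore ≥ 0.1 (below that, the structural twilight zone), ranked and
  truncated to the top 50. Neighbourhoods can be exported as a NEXUS
  distance matrix (distance = 1 − Qscore) and a neighbour-joining Newick
  tree.

See [docs/methods.md](docs/methods.md) for algorithms, parameter defaults
and their rationale.

## Worked example (synthetic, no downloads)

Generate a 27-chain demo set — two ~100-residue families (one all-helix,
one all-strand), each with near-identical cluster members (2% mutations)
and diverged relatives (50% mutations), plus one unrelated coil chain:

```
$ strucphy fixtures --preset family-set --seed 11 --out structs
$ strucphy -v build --input-dir structs --out-db db
INFO strucphy.pipeline: chains read: 27 (from 27 files)
INFO strucphy.pipeline: chains ≥ 50 aa: 27
INFO strucphy.pipeline: clusters: 13
INFO strucphy.pipeline: vetted clusters: 12 (removed 1)
INFO strucphy.pipeline: centroid pairs scored: 66
database written to db
```

The removed cluster is the coil-only singleton, which fails centroid
vetting. Querying the neighbourhood of a helix-family member returns
exactly the five planted relatives (the strand family sits below the 0.1
Qscore cutoff):

```
$ strucphy neighbours --db db --query ha03_A --out-prefix out/ha03
5 hits for ha03_A (centroid ha00_A)
$ head -4 out/ha03_hits.csv
centroid_id,qscore,distance,rmsd,n_aligned,identity_pct,similarity_pct,bit_score,evalue,scop,cath,description
hr04_A,0.988585,0.011414999999999953,0.3224,102,54.9,56.86,98.98,1.66192e-26,N/A,N/A,N/A
hr00_A,0.987348,0.012651999999999997,0.3396,102,46.0,56.0,83.96,5.53247e-22,N/A,N/A,N/A
hr03_A,0.987136,0.012863999999999987,0.3425,102,50.51,54.55,89.74,1.00825e-23,N/A,N/A,N/A
$ cat out/ha03_top5.nwk
((ha00_A:0.000000,hr04_A:0.011605):0.000509,(hr00_A:0.011971,hr02_A:0.012304):0.000656,(hr03_A:0.011062,hr01_A:0.012771):0.001403);
```

One-off pairwise comparison and cluster inspection:

```
$ strucphy compare --pdb1 structs/ha03.pdb --pdb2 structs/hr01.pdb
{"id1": "ha03_A", "id2": "hr01_A", "status": "OK", "qscore": 0.9729920552664983, "rmsd": 0.49981855633166866, "n_aligned": 102, "n1": 102, "n2": 102}
$ strucphy clusters --db db --query ha03_A | head -4
cluster_id member_id  size confidence  qscore_vs_centroid   rmsd  n_aligned
     00007    ha00_A   102       high            1.000000 0.0000        102
     00007    ha01_A   102       high            0.988287 0.3266        102
     00007    ha02_A   102       high            0.985290 0.3666        102
```

On real data, point `--input-dir` at a directory of PDB files, optionally
with `--fasta` for deposited sequence records and `--annotations` for a
SCOP/CATH description table keyed by `member_id`.

## Library use

```python
from strucphy import read_chains, align_structures, build_database, neighbours

db = build_database("structs/", "db/")
hits = neighbours(db, "ha03_A")          # HitList; hits.to_frame() is a DataFrame
a, b = read_chains("structs/ha03.pdb")[0], read_chains("structs/hr01.pdb")[0]
print(align_structures(a, b).qscore)
```
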