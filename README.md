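# bondscan

Quantify hydrogen bonds, salt bridges, and amino-acid use across two
species' protein structure sets, and run the comparative statistics used to
look for signatures of protein temperature adaptation.

Given PDB-format structure models (one per protein, biounit form, ligands
allowed), FASTA files of the corresponding full-length sequences, and a
per-protein model-quality (QMEAN) table, bondscan:

- detects **hydrogen bonds** by pure distance criteria (donor–acceptor
  ≤ 3.5 Å, optional hydrogen–acceptor ≤ 2.5 Å when hydrogens are modeled,
  no angle term) and **salt bridges** (Asp/Glu carboxyl O to Arg/Lys/His
  side-chain N ≤ 4.0 Å);
- builds a per-protein feature table (lengths, QMEAN, bond counts, per-residue
  bond rates, amino-acid counts), applies quality filters (QMEAN cutoff,
  annotation-based deduplication, removal of uncharacterized proteins), and
  pairs orthologs by identical annotation;
- compares species with Mann-Whitney U tests on full sets, ortholog pairs,
  and upper-quantile subsets; produces frequency histograms, threshold
  percentages, and list-overlap statistics;
- runs chi-square tests of amino-acid usage, Spearman correlations of usage
  deviations against residue hydrophobicity/volume ranks, and per-term
  Fisher-exact GO over-representation;
- generates all of its own test inputs synthetically (ideal α-helices,
  salt-bridge dimers, random structures, seeded two-species proteome
  ensembles with planted effects).

## CLI

One YAML config describes both species (see `tests/test_cli.py` for a worked
example):

```yaml
species_a: {label: warm, fasta: warm.fasta, pdb_dir: pdb_warm, qmean: qmean_warm.tsv}
species_b: {label: cold, fasta: cold.fasta, pdb_dir: pdb_cold, qmean: qmean_cold.tsv}
out_dir: out
annotations: annotations.tsv   # optional; protein_id <tab> GO:nnnnnnn [<tab> name]
```

```sh
bondscan quantify --config config.yaml   # feature tables + per-bond reports + filter log
bondscan compare  --config config.yaml   # Mann-Whitney/Spearman report, histograms,
                                         # threshold percentages, list overlap
bondscan usage    --config config.yaml   # amino-acid usage tables + rank correlations
bondscan enrich   --config config.yaml   # GO over-representation of upper-quantile sets
bondscan simulate --seed 3 --out simdir  # synthetic two-species ensemble
```

All outputs are TSV and byte-deterministic for a fixed config and seed.

## Library

```python
from bondscan import read_pdb, detect_hbonds, detect_salt_bridges, HbondParams

model = read_pdb("protein.pdb")
bonds = detect_hbonds(model, HbondParams())          # list of ContactPair
bridges = detect_salt_bridges(model)                 # residue-pair counting
```

See `bondscan.features` for table filtering/subsetting, `bondscan.stats` for
the test implementations (exact small-sample paths included), and
`bondscan.synthetic` for fixture generators.

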