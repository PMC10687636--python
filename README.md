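# cpikit

Analysis toolkit for cysteine-rich carboxypeptidase-inhibitor (CPI) peptides:
sequence curation and mature-region trimming, threshold consensus and
cysteine-spacing motif derivation/scanning, a physicochemical panel,
distance-based phylogeny with bootstrap supports, geometric typing of
inhibitor–enzyme interface contacts, and a seeded synthetic family generator
so every pipeline stage is testable without downloads.

## Modules

| module | what it does |
|---|---|
| `cpikit.records` | `PeptideRecord` + FASTA I/O (headers `id\|species\|source_db`) |
| `cpikit.curation` | inclusion filtering (`redundant`/`incomplete`/`uncharacterized`/`cysteine_pattern`) and trimming to the mature region (cut 3 residues before the first anchor cysteine) |
| `cpikit.motif` | `SpacingMotif` (compact `CXXXCXXXXDCXXXXXCXXC` and PROSITE-like `C-x(3)-C-x(4)-D-C-x(5)-C-x(2)-C` syntaxes), overlap-aware scanning, match rate |
| `cpikit.conservation` | per-column frequencies, MView-style threshold consensus (identity call, else class symbol, else none), motif derivation from conserved columns |
| `cpikit.physchem` | molecular weight (average masses), isoelectric point (bisection on the Henderson–Hasselbalch net charge, Bjellqvist-style pKa set), formal charge (K+R)−(D+E), hydrophobic ratio, Boman index; all constant tables configurable |
| `cpikit.phylogeny` | p/Poisson/Kimura distances with pairwise deletion, deterministic neighbor-joining, column-bootstrap supports, Newick I/O |
| `cpikit.interactions` | PDB parsing (first model, occupancy-resolved altlocs) and typed inter-chain contacts: hydrogen bond, attractive charge, π-π T-shaped, π-alkyl, each with a configurable cutoff |
| `cpikit.synth` | seeded generator of scaffold-bearing families (class-biased spacer segments, hydrophobic tail, optional propeptide, exact violation counts) and motif-free decoys |
| `cpikit.pipeline` | YAML-configured orchestration producing a deterministic TSV report bundle |

## CLI

Installed as both `cpikit` and `cpipipeline` (same entry point):

```bash
cpikit simulate --n 42 --seed 7 --out family.fasta --aln family.aln.fasta --truth truth.tsv
cpikit curate --in family.fasta --out kept.fasta --report rejected.tsv --min-cys 5
cpikit consensus --aln family.aln.fasta --thresholds 100,90,80,70
cpikit motif derive --aln family.aln.fasta
cpikit motif scan --in kept.fasta
cpikit physchem --in kept.fasta --out panel.tsv
cpikit phylo --aln family.aln.fasta --reps 1000 --seed 17 --correction kimura --out tree.nwk
cpikit interactions --pdb complex.pdb --chain-a A --chain-b I --out contacts.tsv
cpikit run --config run.yaml
```

`run.yaml` keys: `fasta`, `aln`, `outdir` (required); `pdb`, `chain_a`,
`chain_b`, `thresholds`, `min_cys`, `anchor_threshold`, `correction`, `reps`,
`seed`, `geometry` (optional). The bundle contains `kept.fasta`,
`rejected.tsv` (id, reason), `consensus.tsv` (column, one call column per
threshold), `freqs.tsv` (column, residue, frequency), `motif.txt` (compact +
PROSITE-like), `match_rate.txt`, `panel.tsv` (id, species, pI, MW_Da, charge,
hydrophobic_pct, boman_kcal_mol), `tree.nwk`, `supports.tsv`,
`interactions.tsv` (when a PDB is given) and `run_log.json`.

Atom selectors use `CHAIN:RESNAME+NUMBER:ATOM`, e.g. `A:ARG127:NH1`.

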