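# Reproducing published per-genome tables

`flocprofiler.supplementary` re-derives a study's printed headline counts
by applying the package's rules to its per-genome supplementary tables.
The tables are not redistributable with the package; place converted copies
under `data/supplementary/` (relative to the repository root) and run

```bash
python -m pytest tests/test_acceptance.py::test_published_supplementary_tables_reproduce
```

or, from Python:

```python
from flocprofiler.supplementary import reproduce_all
print(reproduce_all("data/supplementary"))
```

## Source

For the biofloc MAG study this package was validated against, the
supplementary tables (Table S1–S15) are deposited on FigShare under
doi:10.6084/m9.figshare.25249096, and the genomes at the same record; raw
reads are under SRA accessions SRR24442552–SRR24442559.

## Required files (UTF-8 TSV, header row, `.` = missing)

| file | columns | source table |
|---|---|---|
| `quality.tsv` | `mag_id`, `completeness`, `contamination` | per-MAG assembly statistics (Table S3) |
| `taxonomy.tsv` | `mag_id`, `taxonomy` (full GTDB string) | Table S3 taxonomy column |
| `relative_abundance.tsv` | `mag_id` + one column per biofloc metagenome, RA in percent | Table S6/S8 (biofloc columns only) |
| `novelty_identity.tsv` | `mag_id`, `best_identity` (percent vs EzBioCloud) | Table S5 |
| `gene_content.tsv` | `mag_id`, `symbol` — one row per annotated gene | Table S9 (nitrogen/sulfur gene content) |
| `cazy_counts.tsv` | any table whose numeric cells are CAZyme gene counts | Table S10 |

## Conversion notes (annotation dialects)

* **Symbols**: the engine's controlled vocabulary
  (`src/flocprofiler/data/vocabulary.txt`) uses lowercase subunit symbols
  (`nirS`, `napA`, `soxB`, `dsrA`, ...).  Map DRAM/KOfam output onto them by
  KO: e.g. K00368→`nirK`, K15864→`nirS`, K02567/K02568→`napA`/`napB`,
  K00370/K00371/K00374→`narG`/`narH`/`narI`, K00362/K00363→`nirB`/`nirD`,
  K03385/K15876→`nrfA`/`nrfH`, K17222–K17227→`soxA`/`soxX`/`soxB`/`soxC`/
  `soxY`/`soxZ`, K11180/K11181→`dsrA`/`dsrB`, K01915→`glnA`,
  K00265/K00266→`gltB`/`gltD`.  Collapsed systems (`nas`, `nirA`, `hao`,
  `nxr`, `hzs`, `hdh`, `nif`, `gdh`) absorb any of their subunit KOs.
* **Excel export**: save each sheet as TSV; strip thousands separators and
  `%` signs; percentages stay on the 0–100 scale.
* **Relative abundance**: keep only the 11 biofloc metagenome columns —
  the MfA rule is defined against those samples.
* **CAZy counts**: a long per-gene table also works — any numeric cells are
  summed, so a 0/1 indicator per gene row gives the gene total.

## Expected outcomes

With faithfully converted tables, `reproduce_all` returns the study's
printed counts exactly: 257 high / 260 medium quality, 479 unclassified at
species rank, 184 MfA, 65 novel genera / 48 novel species, 51 sox-complete,
5 sox+rdsr, 128 / 30 denitrification / DNRA marker genomes, 145 GS-GOGAT,
and 7,540 CAZyme genes.  Note the sox+rdsr count from gene content alone
assumes the oxidative orientation that the study confirmed phylogenetically.
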