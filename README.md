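# degenprobe

Design and in-silico validation of **degenerate explorative probes** for
functional DNA microarrays.

Functional gene arrays built from specific probes can only detect the
sequences already in the databases. To monitor a *function* — say, a
ring-hydroxylating dioxygenase in a polluted soil — including the gene
variants nobody has sequenced yet, probes must be designed at the protein
level and written degenerately. `degenprobe` implements that workflow:

1. **Homolog mining** — rank candidate family members of a reference
   protein by local Smith–Waterman score (BLOSUM62, affine gaps 11/1)
   normalized via the Karlin–Altschul transform
   `S' = (λS − ln K)/ln 2`, `E = m·n·2^(−S')`, and prefilter them by
   length divergence before alignment.
2. **Backtranslated consensus** — every column of the protein multiple
   alignment is backtranslated into the degenerate codon covering the
   union of all codons of all residues observed there, written with
   IUPAC ambiguity codes; any fully degenerate position becomes
   **inosine (I)**, the universal-pairing base.
3. **Probe enumeration** — all windows of fixed length (24-mer by
   default) are kept if `degeneracy ≤ D` and inosine fraction `≤ f`,
   where degeneracy counts inosine as 1 (an inosine spot is synthesized
   directly) while the **total degeneracy** counts it as 4 (the number
   of fully specified probes an in-situ array needs). The worst case is
   `D · 4^⌊L·f⌋`. The last base of each probe, usually a wobble
   position, is trimmed.
4. **Specificity screen** — probes are scanned exhaustively (every
   offset, both strands) against a background of CDSs ± 100 nt flanks
   and flagged by **Kane's criteria**: > 75 % identity over the probe,
   or ≥ 15 contiguous identical bases. Flagged hits whose harboring
   gene aligns to the reference protein (six-frame translation) are
   rescued as target-family members; the rest are clustered and counted
   as cross-hybridizations.
5. **Array analysis** — spot intensities are reduced with a spatially
   segmented signal-to-noise statistic: the surface is cut into 16
   sub-squares, random control probes give each square a background
   median `B_position` and dispersion `B_dispersion`, and
   `SNR' = (intensity − B_position)/B_dispersion`. A probe is positive
   when its replicate-median SNR' exceeds 3.

A deterministic simulation module generates protein families, decoy
backgrounds and array feature tables with ground-truth labels, so the
whole pipeline is testable offline.

## Worked example

```python
>>> import degenprobe as dp
>>> dp.backtranslate_column({"R"})          # six Arg codons merge
'MGI'
>>> probe = "GTITGYAAYTAYCAYGGITGGGT"       # 23-mer, phnA1a region A
>>> dp.degeneracy(probe)                    # inosine counted once
16
>>> dp.total_degeneracy(probe)              # inosine expanded: probes to print
256
>>> aln = dp.ProteinAlignment(records=(("r", "HGW"),), reference_id="r")
>>> dp.build_consensus(aln).seq
'CAYGGITGG'
>>> dp.max_total_degeneracy(dp.STRATEGY_1)  # L=24, D=129, inosine 25%
528384
>>> dp.max_total_degeneracy(dp.STRATEGY_2)  # L=24, D=258, inosine 9%
4128
```

`degeneracy 16` means the probe covers 16 coding variants at the design
threshold; `total_degeneracy 256` is the number of fully specified
oligos actually synthesized for that spot on an in-situ array.

From the shell, the same pipeline is:

```bash
degenprobe simulate --seed 5 --what family        # synthetic family fixture
degenprobe design sim_family.fasta --degeneracy-max 258 --inosine-max 0.09
degenprobe build-db genome.fasta genes.gff3       # CDS ± 100 nt background
degenprobe screen probes.tsv crosshyb_db.fasta ref.fasta --select 2
degenprobe array-snr features.tsv --threshold 3
```

## Layout

```
src/degenprobe/
  alphabet.py   IUPAC/inosine algebra, genetic code, backtranslation
  homologs.py   local-alignment homolog mining and prefilters
  design.py     consensus construction, probe enumeration, ranking
  screen.py     background DB, Kane scanning, family rescue, clustering
  arrays.py     segmented SNR' analysis
  simulate.py   deterministic synthetic fixtures
  catalog.py    the 16-probe PAH reference catalog
  io.py, cli.py formats and the command line
```
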