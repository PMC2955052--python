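# Methods

## Backtranslation and the degenerate alphabet

A column of a protein multiple alignment is mapped to the degenerate
codon covering the union of all codons of all amino acids present in it
(standard genetic code by default; any NCBI translation table can be
loaded). The union is taken position-wise and written with IUPAC
ambiguity codes; a position whose base set is {A,C,G,T} is written as
inosine (`I`) rather than `N`, because inosine pairs with all four bases
and a single inosine residue can be synthesized in place of four
variants. This choice is why the method distinguishes two variant
counts:

* **degeneracy** — product of base-set sizes with `I` counted as 1.
  This is the design-threshold scale: an ex-situ array can hold inosine
  probes directly, so inosine does not multiply synthesis cost there.
* **total degeneracy** — the same product with `I` counted as 4; the
  number of fully specified probes an in-situ synthesis platform must
  print for the spot.

Consequences, all covered by tests: `degeneracy ≤ total_degeneracy`
with equality iff the probe has no inosine, and the expansion routine
returns exactly `total_degeneracy` (or `degeneracy` in inosine-keeping
mode) distinct sequences, in lexicographic order.

Choices the merging rule needed that the column data do not force:
STOP codons are excluded from codon unions (a column of only STOPs is
an error); the protein ambiguity codes B and Z expand to {D,N} and
{E,Q}; `X` and gap characters contribute nothing to a column, and
columns where the *reference* is gapped are dropped entirely, so the
consensus coordinate system coincides with the ungapped reference CDS
(1-based, 3 nt per residue). IUPAC merging is deliberately lossy: the
merged codon may encode amino acids not present in the column, but it
always covers the full codon union (a tested invariant).

## Probe enumeration and the two strategies

Windows of the configured length (default 24 nt) slide one nucleotide
at a time — probes need not be codon-aligned. A window is kept when
`degeneracy ≤ D` **and** inosine count / length `≤ f`; both comparisons
inclusive. Inclusive is the only reading consistent with the worst-case
arithmetic `D · 4^⌊L·f⌋`, which for the two standard strategies gives
129 · 4⁶ = 528,384 (D=129, f=25 %) and 258 · 4² = 4,128 (D=258,
f=9 %, where ⌊24·0.09⌋ = 2). The last base of each probe — usually a
wobble position or inosine — is trimmed by default, giving 23-mers.

Candidate ranking applies three criteria in sequence: fewest
cross-hybridization clusters, lowest total degeneracy, and, when `k`
probes per gene are requested, maximal spread along the reference
(greedy: the top candidate is fixed; each later pick maximizes its
minimum start-coordinate distance to the picks so far). The greedy rule
is this package's codification of "target different regions"; no
closed-form rule exists to inherit.

## Specificity screening

The background database holds one record per CDS, extended by 100 nt
(configurable) on each side — flanks are part of the hybridization pool
because transcripts carry UTRs — truncated at sequence boundaries and
reverse-complemented for minus-strand features so all records read
5'→3' along the coding strand.

Kane's empirical rules for long oligos define cross-hybridization risk:
identity > 75 % over the probe, OR an identical stretch of ≥ 15
contiguous bases. "Longer than 15" is ambiguous in the source material;
the stricter ≥ 15 reading is the default and the cutoff is
configurable. Screening is an exhaustive ungapped scan of every offset
of every record on both strands, implemented over 4-bit base-set masks:
a probe position matches a target base iff the base is in the
position's IUPAC set, with inosine matching everything and counting as
a match for both statistics. This scan strictly dominates the
heuristic BLAST cascade it replaces in sensitivity, at desk scale, and
removes the external-binary dependency.

Because the expanded variants of a degenerate probe form a cartesian
product over independent positions, the best identity and longest
stretch over *all* variants at an offset equal the degenerate base-set
match at that offset; the scan is therefore an exact aggregation of
per-variant evaluation (tested against a per-variant brute force).
Each hit reports the realized best-matching variant. One hit is kept
per record per strand (best identity).

Flagged hits are rescued as target-family members when the harboring
record's best six-frame-translation local alignment against the
reference protein reaches a bit-score threshold; by default the
threshold is the bit score at which the estimated E-value over the
pair's search space falls to 1e-10, and an absolute bit-score override
is available. Remaining cross-hybridization hits are single-linkage
clustered by ungapped identity (default 90 %) of the regions around the
hit positions (± one probe length), and a candidate's
cross-hybridization count is the number of *clusters*, so a family of
near-identical background genes counts once.

## Homolog mining

Scoring is local Smith–Waterman with BLOSUM62 and affine gaps (open 11,
extend 1; a length-k gap costs 11 + k), normalized with the standard
gapped-BLOSUM62 Karlin–Altschul constants λ = 0.267, K = 0.041. The
resulting E-value estimates share BLAST's scale but not its
length-corrections or seeding, so they are *estimates*; selection
thresholds are applied on this estimated scale. Ties rank by subject
id. The size-divergence prefilter keeps a candidate iff its length is
within 20 % (inclusive, configurable) of the reference length; it
exists to limit indel regions in the downstream alignment. The
implementation is verified against an independent quadratic-time Gotoh
dynamic program on short sequences.

## Array analysis

The array surface is cut into `rows × cols` sub-squares (default 4 × 4
= 16) over the [min, max] ranges of the spot coordinates, half-open
intervals with the last closed and boundary spots assigned upward.
Within each square, random control probes give `B_position` (median)
and `B_dispersion`. The dispersion estimator is pluggable —
`1.4826 × MAD` (default, robust to spike contamination), `IQR/1.349`,
or the sample SD — because the original's exact estimator is not
specified in closed form; the MAD choice is a documented stand-in. The
dispersion is floored at a small epsilon (default 1e-9 intensity units)
so constant backgrounds do not divide by zero, and squares with fewer
than 10 random probes fall back to whole-array random-probe statistics
with a logged warning.

`SNR' = (intensity − B_position)/B_dispersion` is computed per feature
with its own square's statistics; replicate SNR' values (3 replicates
on the physical design) are summarized by their median, and the
positive call is **strict**: median SNR' > 3, so a probe sitting
exactly at 3 dispersions is negative. The whole chain is invariant
under global rescaling of intensities and under adding a constant
within a square — tested properties that make the calls comparable
across scanner gains.

Two-channel experiments are analyzed per channel; no ratio
normalization is applied. Feature tables are plain TSV
(`probe_id, x, y, intensity, probe_class, replicate`); a reader for
the documented `.pair`-style column layout (`PROBE_ID, X, Y, PM`) maps
onto it, classifying ids with a `RANDOM` prefix as controls.

## Synthetic data

The generators are pure functions of (config, seed) and emit
ground-truth sidecars.

* **Protein families**: a uniform-random reference of 150–500 residues
  and 4–10 members derived by per-site substitution (default rate 0.1,
  giving ≈ 90 % pairwise identity, typical of the within-family
  divergence the probe design is meant to span) and optional single
  -residue indels; coding DNA is drawn per codon-usage weights (uniform
  over synonymous codons by default).
* **Backgrounds**: uniform-random CDS-like records (defaults: 100
  records of 1 kb) plus decoys engineered against a given probe to
  violate exactly one specificity criterion: `identity` decoys spread
  mismatches (placed only at non-universal probe positions, mutated to
  bases outside the position's set) evenly so no match run reaches the
  stretch rule; `stretch` decoys keep an exact k-mer and force
  mismatches everywhere else. Ground-truth identity and stretch are
  computed against the degenerate probe, exactly as the screen will
  measure them; the screen may legitimately report a longer stretch at
  a shifted offset, so truth values are lower bounds for flagging.
* **Arrays**: spots uniform on the unit square, intensity = baseline +
  planar gradient(x, y) + Gaussian noise + spike, with spikes in units
  of the noise SD; targets get 3 randomly placed replicates, controls
  one spot. At the acceptance scale (8,000 null probes, threshold 3,
  median of 3 replicates) the expected false-positive count is
  ≈ 8000 · 3p²(1−p) + p³ with p = Φ(−3) ≈ 0.00135, i.e. ≈ 0.04 < 1,
  which is why the fixed-seed test asserts zero.

What the fixtures do **not** model: hybridization thermodynamics,
sequence-dependent sensitivity, scanner saturation and spatial
artifacts beyond a smooth gradient, or database-scale background
diversity. Passing tests demonstrate algorithmic correctness of the
design/screen/call chain, not wet-lab probe performance.

## Numerical and engineering choices

* Expansion output is lexicographically sorted, and all tie-breaks
  (hit ordering, ranking, cluster numbering) are deterministic, so
  reruns are byte-identical.
* Expansion and screening refuse above a configurable variant cap
  (default 10⁶) instead of exhausting memory.
* The exhaustive scan is O(probe × record) per strand with vectorized
  match matrices; desk-scale backgrounds (hundreds of kb) screen in
  seconds. Scaling to EMBL-division-size databases would need an
  indexed pre-filter, which is out of scope.
* Reported coordinates are 1-based inclusive everywhere at the
  interfaces; internal arrays are 0-based.

## Known limitations

* E-values are Karlin–Altschul estimates, not NCBI BLAST output; Table
  thresholds expressed as BLAST E-values are honored on the estimated
  scale only.
* Melting-temperature/thermodynamic scoring is not implemented.
* The dispersion estimator of the original background-noise procedure
  is approximated by the scaled MAD (see above).
* Probe ids are synthesized as `<prefix>_<index>` with variant ordinals
  appended on expansion; no database persistence layer is provided.
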