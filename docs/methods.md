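# Methods

## Alignment model

`flowalign` computes the optimal local alignment between a nucleotide query
and a protein target under an extended Smith-Waterman-Gotoh model in which
one amino acid may be matched by 1, 2, 3, 4 or 5 query nucleotides. Widths
other than 3 imply a frame-shift: 4/5 delete one/two nucleotides to recover
a codon, 2/1 insert one/two. Only the three forward frames are searched;
the CLI's `--both-strands` option re-runs the aligner on the
reverse-complemented read (with its flowgram reversed and complemented) and
reports the better strand.

Scores are floats in the half-bit units of the substitution matrix
(BLOSUM62 default, loaded through Biopython; NCBI-format matrix files are
accepted). Triplets containing `N` translate to `X` and score through the
matrix's `X` entries; stop-translating triplets score a fixed −16,
strictly worse than any BLOSUM62 entry, so optimal alignments never run
through a stop while the DP total order stays well defined. The stop score
is a package choice — nothing in the model constrains it beyond being
prohibitively negative.

### Gap states

Protein-space gaps are affine (`G0 = 8` open, `Ge = 2` extend by default)
in both directions: `E` consumes a residue against a gap, `H` consumes a
whole codon (3 nucleotides). `H` references column `j-3` and is undefined
for `j < 3` at gap opening; those cells hold the floor value. Frame-shift
events exist only inside the width-1/2/4/5 matches, so a protein gap can
never merge with a frame-shift into one hybrid event; the parameter
constraint `S*h + D*h > G0` (below) keeps the two regimes separated
economically as well.

## Position-specific frame-shift penalties

A frame-shift pays the single (`S`) or double (`D`) gap penalty. Two
simultaneous events in one window are "grouped" (adjacent deletions, or two
insertions at one gap position) and pay `D`, or "split" (two separate
locations) and pay the sum of the two independent single penalties.

At homopolymers the penalty is discounted. For a flowpeak `p` whose call is
`n`, the deviation required to have called `m` instead is

    Dev = p - (m + 0.5)   if m < n
          0               if m = n
          (m - 0.5) - p   if m > n

clamped at zero. The discount factor is `f = 1 - Dev/(k * max(n, 1))`,
clamped to [0, 1], and the penalty paid is `P0 - P0*(1-h)*f`: full price at
`f = 0`, floor `P0*h` at `f = 1`. `k` is therefore the relative deviation
at which the full penalty applies (0.4 signal units for a 2-mer at
`k = 0.2` — the quantity `scripts/acceptance.py` recomputes).

Which events are discounted:

- **Deletions** — always priced against the deleted base's flowpeak; with
  flow data the call `n` is the rounded peak of that base's own flow (robust
  when an undercalled separator merges two runs in the called sequence),
  without flow data `n` is the homopolymer run length and `p = n`.
- **Grouped double deletions** — discounted only when both bases come from
  the same flow (same run for FASTA input), using `m = n - 2`; otherwise
  full `D`.
- **Insertions** — discounted when the inserted nucleotide extends a
  flanking homopolymer (`m = n + 1`, or `n + 2` for a grouped double of the
  same nucleotide), or, with flow data, when a zero flow of that nucleotide
  lies strictly between the flanking bases' flows (priced by that zero
  flow's value with `n = 0`). Any other insertion, and grouped doubles of
  two different nucleotides, pay the full penalty.

In `neutral` mode the discount is disabled entirely (`f = 0` everywhere),
giving a constant-penalty frame-shift model with separate single and double
costs.

With `p = n` (FASTA input) the up-call and down-call deviations are both
0.5, so insertion and deletion discounts coincide at every integer peak and
the penalty decreases monotonically with run length — long homopolymers are
cheap to correct even without flow data.

### Insertion validation (`-V`)

Because the read is generated by a known flow order, an insertion of a
nucleotide whose reagent was never flowed between the two flanking peaks is
implausible. With validation on, inserted nucleotides are restricted to
those flowed strictly between the flanking bases' flows, plus the flanking
nucleotides themselves (run extension is always allowed); read ends permit
all four. For FASTA input the flow positions are reconstructed by
simulating the default order `TACG` over the called sequence.

### Parameter validity

`validate_params` rejects `D > 2S` (two single gaps would always undercut a
grouped double, and the DP cannot track repeated corrections of one
homopolymer) and `S*h + D*h <= G0` (the cheapest single-plus-double
frame-shift combination must cost more than opening a protein gap, so
corrections cannot impersonate protein gaps). In neutral mode the same
bound applies with `h = 1`. Mode defaults — neutral `S8/D15`, fasta454
`S12/D24/h0.5/k0.6`, flow454 `S20/D40/h0.3/k0.4/V` — all satisfy both.

## Query profile and kernel

`m_w` does not depend on the protein, so all five widths are precomputed per
query position and residue into a dense `(5, L, 21)` array (20 residues
plus `X`). Candidate pricing is precomputed per read into per-base deletion
and per-gap insertion price tables, and the profile is assembled with
vectorised numpy over all windows; cells whose window would cross the read
start hold −inf. The DP kernel is a straightforward triple loop compiled
with numba (an identical pure-Python path is used if compilation is
unavailable). Traceback stores no pointers: at each cell the predecessors
are re-evaluated in the fixed order `m1..m5, E, H` and the first exact match
is taken, which together with the candidate tie-break (fewer events, then
leftmost position, then lexicographically smallest inserted nucleotides)
makes output fully deterministic. Traceback stops at cell score 0 even when
a zero-scoring match path exists. Ties for the global maximum cell resolve
to the smallest (i, j) in row-major order; within `E`/`H`, opening is
preferred over extending on exact ties.

Coordinates are 0-based half-open internally; the text output uses 1-based
inclusive positions. `nGaps` counts frame-shift gap *openings*: singles
and grouped doubles count one, split doubles two. Coverage is aligned query
nucleotides over query length.

## Brute-force oracle

`brute_force_align` re-derives every candidate triplet by direct
combinatorial enumeration and evaluates the recurrences by plain memoised
recursion over `(i, j, state)` — no query profile, no compiled kernel, no
traceback. It is capped at 6 residues × 20 nucleotides and exists purely as
an independent check; the test suite asserts exact score agreement with the
production path on random instances across all modes and parameter draws.

## Synthetic benchmark

The benchmark measures how well each mode recovers simulated homopolymer
indels, scored by MCC.

- **Seed**: a uniform-random coding sequence of 1950 nt (650 codons, no
  internal stops) stands in for a typical single-ORF viral template; any
  user-supplied coding FASTA can replace it for replication against a real
  locus. Reads of 350 nt (the classic 454 Titanium scale) are drawn from
  uniformly placed windows, forward strand.
- **Targets**: the translated seed is mutated in protein space to fixed
  identities; substituted positions are uniform without replacement and
  replacements are drawn with probability proportional to `2^(s/2)` for the
  half-bit BLOSUM score `s`, using the BLOSUM level nearest the target
  identity among those Biopython ships (90, 80, 62, 50, 45; 70 maps to 62).
  This inverts the log-odds up to the background frequencies, which is
  sufficient to make conservative substitutions dominate.
- **Noise**: positive flows draw `Normal(n, 0.08 + 0.05 n)` truncated at
  zero; zero flows draw `|Normal(0, 0.12)|`; the called length is the
  rounded peak and every call differing from the template is recorded as
  ground truth. These defaults give ≈1 indel per 350-base read (computed
  from the normal tails), the error-rate scale of 454 Titanium data. The
  simulator is *not* an instrument model: it has no quality scores, no
  carry-forward/incomplete-extension chemistry, no read-length decay, and
  its noise is independent across flows. Absolute MCC values therefore
  characterise this generator only; the meaningful benchmark outputs are the
  *relative* statements (mode ordering, flow-aware vs neutral gap), which
  are exactly what the acceptance test asserts.
- **Scoring**: a predicted deletion is correct if it falls inside the read
  span of an overcalled flow with the right nucleotide; a predicted
  insertion if it inserts the right nucleotide at a gap adjacent to (or
  inside) the remaining span of an undercalled flow — so correcting the
  adjacent homopolymer instead of the right one yields one FP and one FN.
  Truth events outside the aligned region are ignored; true negatives are
  the remaining aligned read positions (base-space counting). MCC uses the
  standard formula with the zero-denominator → 0 convention.

Problem sizes in the shipped tests (1000 reads × 4 identities × 3 modes,
650-residue targets) were chosen as the smallest configuration at which the
per-identity MCC estimates are stable to well under the margins being
asserted; the whole benchmark runs in about two minutes on one CPU.

## Known limitations

- No heuristic prefilter: every query-target pair pays the full DP; use an
  external seeded search to shortlist candidates for large databases.
- No homopolymer correction tracking: as in the model's constraints above,
  the same run can in principle be corrected in two adjacent windows; the
  parameter validity rules are what keep this from being profitable.
- Only the standard genetic code; no E-value statistics; SFF index blocks
  are not parsed (flow data and clipping are).
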