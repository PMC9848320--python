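# Methods

This note describes what `astascan` computes and why, module by module. All
empirical statements here are recomputed by the test suite
(`tests/test_acceptance.py`) or the acceptance script
(`scripts/acceptance.py`); none are imported from external runs.

## 1. Motif grammar (`astascan.motifs`)

Astacin identification is anchored on five short motifs. Each is encoded as
a `MotifSpec`: an ordered list of positions that are either wildcards,
**required** anchors (must match exactly), or **substitutable** anchors. A
substitutable anchor may be replaced by a *conservative* alternative —
defined as a residue pair with a strictly positive off-diagonal BLOSUM62
score — and each motif instance is allowed at most two such substitutions.
`X` in an input sequence matches only wildcards. Matching is
case-insensitive; non-residue characters raise `AlphabetError`.

| motif | pattern | required anchors | substitutable anchors |
|---|---|---|---|
| zinc site | `HEXXHXXGXXH` | His1, Glu, His2, His3 | Gly |
| family Glu | `E` at His3 + 1 | Glu (exact) | — |
| acidic cleft | `XXRXDRD` at His3 + 2 | — | R, D, R, D |
| Met-turn | `SIMHY`, start in His3 + [20, 80] | Met (+2), Tyr (+4) | S, I, H |
| latency | `FXGDI` in the prodomain | Asp (+3) | F, I |

`find_zinc_site` composes the first four into a single verdict: it iterates
over zinc-motif candidates and accepts the first one whose family Glu,
`XXRXDRD` and `SIMHY` criteria all hold (nearest `SIMHY` in the window
wins). Failure returns a `ZincSiteRejection` listing *all* failed criteria
of the best candidate as reason codes, never an exception.

The BLOSUM62 table ships with the package as plain text (the canonical
24-letter matrix); a unit test asserts entry-for-entry equality with
Biopython's copy.

## 2. Zymogen validation (`astascan.zymogen`)

The catalytic domain (CD) is delimited arithmetically from the anchors:
`cd_start = His1 − 95`, `cd_end = Tyr_ligand + 60`, clamped to the sequence
(clamping sets a `truncated` flag, reason `cd_truncated`). The defaults
reproduce the archetypal ~200-residue domain: His1 at mature position 92,
family Glu at 103, Tyr the fifth zinc ligand at Met-turn + 2. CD lengths
outside 170–260 give `cd_length_out_of_window`.

Cysteines are censused over the CD; the N-terminal subdomain is everything
before the motif Gly. The archetype carries three N-subdomain cysteines plus
one in the C-subdomain (two potential disulfides); hatching-enzyme-like
astacins carry an **extra pair** (`n_subdomain_cys_extra ≥ 2`).

The prodomain runs from `signal_end` (the annotated signal-peptide length;
signal peptides are *not* predicted) to `cd_start`. Its length must lie in
34–486 (`pro_too_short` / `pro_too_long`; absence is `pro_missing`). The
latency switch is typed from the `FXGDI` hit nearest the activation site:
present → `aspartate` (the accepted state); absent but prodomain contains a
Cys → `cysteine` (the bacterial pattern, rejected with
`no_latency_switch` and flagged `xenologue_flag`); neither → `none`.
Non-holozoan clade metadata also sets the xenologue flag without by itself
rejecting the sequence.

All outcomes are reported as a fixed ten-code vocabulary
(`REASON_CODES`); `validate_astacin` is deterministic and total.

## 3. Subfamily classification (`astascan.domains`)

Profile-level CUB/MAM/TRAF detection is delegated to external tools and
consumed as a hit table (1-based inclusive on disk). The six-cysteine EGF
and ShKT cassettes have built-in scanners: a sextet of consecutive
cysteines is EGF when its span is 35–50 and all five inter-cysteine gaps
fall in the canonical classes `(3–14, 3–7, 1–16, 1–2, 8–23)`; otherwise
ShKT when the span is 28–45. Matching is greedy left-to-right, hits never
share a cysteine, EGF has priority on ambiguity.

Classification considers only hits starting at or after `cd_end` and applies
a fixed precedence (most specific signature first): `meprin_like`
(MAM and TRAF; optionally MAM alone with `mam_only_meprin`) → `BTP`
(≥ 3 CUB) → `hatching_like` (extra CD Cys pair, ≤ 2 CUB) → `shkt_astacin`
(any ShKT) → `basic` (no downstream domains) → `unclassified`. `TM` sets a
membrane flag; unknown domain names pass through, never fatal.

## 4. Phylogenetics (`astascan.phylo`)

Built from four explicit primitives, each tested against an independent
oracle:

* **Pairwise alignment** — global three-state Gotoh dynamic programming
  under BLOSUM62 with affine gaps: a run of length L costs
  `gap_open + (L−1)·gap_extend` (defaults 10 / 0.5). Tie-breaking is
  deterministic (diagonal > up > left). Verified against exhaustive
  alignment-path enumeration (all lengths ≤ 8) and against Biopython's
  `PairwiseAligner` scores.
* **Progressive MSA** — guide order from scipy single-linkage clustering on
  3-mer distances; profile–profile merging with mean-of-pairs column scores
  (gap columns score 0). De-gapping any output row recovers its input
  exactly.
* **Distances** — per-pair mismatch fraction *p* over gap-free column
  pairs; optional Kimura protein correction `d = −ln(1 − p − p²/5)`, capped
  at 10 once `p ≥ 0.85`. Pairs with no comparable columns raise
  `UndefinedDistanceError` (in bootstrap replicates they fall back to the
  cap).
* **Neighbor joining** — standard Q-criterion agglomeration; ties broken by
  the lexicographically smallest pair of subtree representative ids;
  negative branch lengths clamped to zero with the deficit shifted to the
  sister edge; final trifurcation at the root. On additive matrices NJ is
  exact: 100/100 random trees (≤ 12 leaves) are recovered with
  Robinson–Foulds distance 0.

**Bootstrap** resamples alignment columns with replacement — exactly
`n_reps` replicates (default 100) from one seeded `numpy` generator — and
annotates each internal edge with the percentage of replicates containing
the same bipartition. Bipartitions are canonicalised (side not containing
the lexicographically smallest leaf) and trivial splits (either side < 2)
are excluded; `robinson_foulds` agrees with dendropy's symmetric difference
on random tree pairs. Trees serialise to Newick with supports as internal
labels and branch lengths to six decimals; the parser round-trips exactly.

## 5. Synthetic cohorts (`astascan.simulate`)

The generator emits precursors from the family grammar itself, so every
pipeline stage has exact ground truth. Defaults **are** the study
conditions; they were fixed before any evaluation and never tuned to
outcomes:

* signal: `M` + 19 hydrophobic residues (`signal_length = 20`);
* prodomain: uniform 34–486 residues with `FXGDI` ending 10 residues before
  the activation site;
* CD: His1 at offset 95, sampled His3→`SIMHY` distance 25–70 (archetype
  ≈ 45), 59-residue tail after the Tyr ligand — CD lengths 194–239; Cys at
  offsets 41/63/83 plus one C-subdomain Cys (hatching adds a pair at
  50/70);
* downstream cassettes per subfamily (BTP: `CUB×3, EGF, CUB, EGF, CUB`;
  meprin: `MAM, TRAF, EGF, TM`; ShKT and hatching variants);
* background residues are uniform excluding Cys, and a sanitisation pass
  scrambles any *accidental* motif instance that would shadow the planted
  ground truth (this is part of the construction, not tuning).

Decoys each break **exactly one** determinant (9 classes, from zinc-motif
ablation to cysteine-switch prodomains) and carry the reason code the
validator must produce. At mutation rate 0 the generator–validator closure
is exact over 1,000 records: 100% positive acceptance, 0% decoy acceptance,
100% anchor recall.

`evolve_along_tree` mutates each site per branch with probability
`rate × branch_length` (capped at 0.95); with anchor protection on,
protected positions are immutable and substitutions are conservative-only.
Evolving an archetype CD along random 8-leaf trees at rate 0.05 per site
per branch, MSA + NJ recovers the true topology in ≥ 90% of seeds
(49/50 at `--seed 1`).

A fixed 21-record benchmark panel spans 18 animal-phylum clades across the
five subfamilies plus one bacterial cysteine-switch comparator; the
validator accepts all 20 astacins and rejects the comparator with
`no_latency_switch` and the xenologue flag.

## 6. Pipeline and formats (`astascan.pipeline`, `astascan.io`)

`run_pipeline` = read FASTA (+ metadata TSV, domain TSV) → validate →
classify → write `report.jsonl` / `summary.tsv` → align accepted CDs →
`distances.phylip` → bootstrapped `tree.nwk` → `clade_summary.tsv`
(per-clade leaf counts and monophyly). Provided domain hits win over
overlapping same-name pattern hits. With < 2 accepted records the tree step
is skipped; with none the run stops with status `no_astacins` (CLI exit
code 3). Reruns are byte-identical given the same inputs and config; the
full configuration round-trips through YAML.

Internally every coordinate is 0-based half-open; every file written to
disk is 1-based inclusive, converted only at the I/O boundary. The FASTA
reader is intentionally strict (it reports 1-based line numbers, tolerates
CRLF, rejects headerless data and empty records) because curation quality
depends on input hygiene.

## 7. Parameter defaults and rationale

| parameter | default | rationale |
|---|---|---|
| conservative substitutions per motif | ≤ 2 | tolerate drift at non-essential positions without admitting non-astacins |
| `SIMHY` window past His3 | 20–80 | brackets the archetype distance (~45) across the family |
| CD offsets (n_up, c_down) | 95, 60 | close exactly on the archetype anchor geometry |
| CD length window | 170–260 | family CDs cluster near 200 residues |
| prodomain bounds | 34–486 | observed family range |
| `signal_end` | 0 | signal peptides are not predicted; pass the annotated length (generated cohorts use 20) |
| gap open / extend | 10 / 0.5 | standard BLOSUM62 protein-alignment penalties |
| distance correction | Kimura, cap 10 at p ≥ 0.85 | avoids undefined logs at saturation |
| bootstrap replicates | 100 | the conventional support resolution (1% steps) |

## 8. Limitations

* Synthetic sequences are grammar-faithful but not statistically realistic
  proteins (uniform background, no indel evolution, no compositional bias);
  real-data performance is not claimed.
* CUB/MAM/TRAF detection is out of scope — only their *hit tables* are
  consumed; the built-in EGF/ShKT scanners are cysteine-framework patterns,
  not profile HMMs.
* Signal peptides are not predicted; `signal_end` must come from upstream
  annotation (defaulting to 0 merges the signal into the prodomain, which
  only matters within 20 residues of the length bounds).
* The progressive MSA is a guide-tree heuristic without iterative
  refinement, and NJ is a distance method: exact on additive inputs, but no
  likelihood model of protein evolution is implied.
* Hatching-enzyme detection rests on the extra N-subdomain cysteine pair;
  lineages that achieve hatching function without it would classify as
  `basic`.
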