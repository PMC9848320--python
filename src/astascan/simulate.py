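"""Synthetic astacin precursor cohorts with full ground truth.

Every stage of the pipeline is testable without database downloads: the
generator assembles precursors from the family's own grammar — a 20-residue
hydrophobic signal peptide, a prodomain (34-486 residues) carrying the FXGDI
latency motif with its zinc-blocking Asp, a catalytic domain with exactly one
zinc-binding consensus, the family Glu at His3+1, XXRXDRD at His3+2, SIMHY in
the archetypal window and four (or, for hatching-enzyme-like forms, six)
cysteines, and the subfamily's downstream cassette (five CUB + two EGF for
BTPs; MAM + TRAF + EGF + TM for meprins; ShKT cassettes; an extra CD Cys pair
for hatching enzymes). Negative decoys carry the zinc motif but break exactly
one astacin-specific determinant each, so the validator must reject them with
the intended reason code.

Background residues are uniform over the 20 amino acids except that random
filler excludes cysteine (so the cysteine census is exactly the planted one)
and a post-assembly sanitization pass scrambles any accidental motif instance
that would shadow the planted ground truth. Determinism: all randomness flows
through the supplied numpy Generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import RESIDUES
from .domains import DomainHit
from .io import SequenceRecord, write_domain_hits_tsv, write_fasta, write_metadata_tsv
from .matrices import blosum62
from .motifs import FXGDI, SIMHY, ZINC_MOTIF, scan_motif
from .phylo import PhyloTree, TreeNode

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_canonical_cd",
    "make_precursor",
    "make_decoys",
    "make_cohort",
    "evolve_along_tree",
    "random_binary_tree",
    "benchmark_panel",
    "write_cohort",
]

SUBFAMILIES = ("basic", "BTP", "meprin_like", "hatching_like", "shkt_astacin")
DECOY_CLASSES = (
    "zinc_motif",
    "family_glu",
    "xxrxdrd",
    "simhy",
    "pro_too_short",
    "pro_too_long",
    "pro_missing",
    "no_latency_switch",
    "cys_switch",
)
_DECOY_REASON = {
    "zinc_motif": "zinc_motif_missing",
    "family_glu": "family_glu_missing",
    "xxrxdrd": "xxrxdrd_missing",
    "simhy": "simhy_missing",
    "pro_too_short": "pro_too_short",
    "pro_too_long": "pro_too_long",
    "pro_missing": "pro_missing",
    "no_latency_switch": "no_latency_switch",
    "cys_switch": "no_latency_switch",
}

_BG = RESIDUES.replace("C", "")  # filler alphabet: no accidental cysteines
_HYDROPHOBIC = "AAFFIILLLLMVVW"

# Fig. 4-style cross-phyla benchmark panel: 20 metazoan astacins spanning the
# animal phyla plus one bacterial cysteine-switch comparator.
BENCHMARK_PANEL = (
    ("MEPb_HOMSA", "Vertebrata", "meprin_like"),
    ("MEPb_PETMA", "Vertebrata", "meprin_like"),
    ("SMD_SACKO", "Hemichordata", "basic"),
    ("CUB_ASTRU", "Echinodermata", "BTP"),
    ("LysM_RAMVA", "Tardigrada", "basic"),
    ("TLD_DROME", "Arthropoda", "BTP"),
    ("LASTMAM_LIMPO", "Arthropoda", "meprin_like"),
    ("AST_ASTAS", "Arthropoda", "basic"),
    ("HCH1_CAEEL", "Nematoda", "hatching_like"),
    ("ShKT_PRICA", "Priapulida", "shkt_astacin"),
    ("CUBMAM_BUGNE", "Bryozoa", "BTP"),
    ("ShKT_LINUN", "Brachiopoda", "shkt_astacin"),
    ("AST_DIMGY", "Annelida", "basic"),
    ("MAMEGF_BRAPC", "Rotifera", "meprin_like"),
    ("ShKT8_MYTCO", "Mollusca", "shkt_astacin"),
    ("ShKT_SCHMD", "Platyhelminthes", "shkt_astacin"),
    ("ASTLD_MNELE", "Ctenophora", "basic"),
    ("HAS7_HYDVU", "Cnidaria", "shkt_astacin"),
    ("CUBEGF_TRIAD", "Placozoa", "BTP"),
    ("IG4_AMPQE", "Porifera", "basic"),
)
BENCHMARK_COMPARATOR = ("MYR_MYRSP", "Bacteria", "cys_switch")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for cohort generation.

    ``simhy_offset_window`` samples the His3 -> SIMHY distance (the archetype
    sits near 45); with the fixed CD geometry (His1 at CD offset 95, tail of
    59 residues after the Tyr ligand) this yields CD lengths of 194-239
    residues. Prodomain lengths are uniform over the family's 34-486 range.
    """

    n_taxa: int = 20
    subfamily_mix: dict = field(
        default_factory=lambda: {s: 0.2 for s in SUBFAMILIES}
    )
    pro_length_bounds: tuple = (34, 486)
    simhy_offset_window: tuple = (25, 70)
    signal_length: int = 20
    mutation_rate: float = 0.0
    anchor_protection: bool = True
    decoy_fractions: dict = field(
        default_factory=lambda: {c: 1.0 / len(DECOY_CLASSES) for c in DECOY_CLASSES}
    )

    def __post_init__(self):
        if abs(sum(self.subfamily_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subfamily mix proportions must sum to 1")
        if abs(sum(self.decoy_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("decoy fractions must sum to 1")
        lo, hi = self.pro_length_bounds
        if not (0 < lo <= hi):
            raise ValueError("prodomain bounds must be ordered and positive")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator planted, in precursor coordinates."""

    anchors: dict
    cd_span: tuple
    pro_span: tuple
    domain_hits: tuple
    subfamily: str
    decoy_class: str | None = None
    intended_reason: str | None = None

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["domain_hits"] = [
            {"name": h.name, "start": h.start, "end": h.end} for h in self.domain_hits
        ]
        return d


def _bg(rng, n: int) -> str:
    return "".join(rng.choice(list(_BG), size=n)) if n > 0 else ""


def _hydrophobic(rng, n: int) -> str:
    return "".join(rng.choice(list(_HYDROPHOBIC), size=n))


def make_canonical_cd(cfg: GeneratorConfig, rng, hatching: bool = False):
    """Emit one catalytic domain and its CD-relative ground truth.

    Geometry: His1 at offset 95, zinc motif HE..H..G..H through offset 105,
    family Glu at 106, XXRXDRD at 107-113, SIMHY starting a sampled distance
    past His3, Tyr ligand two positions after the Met-turn, and a 59-residue
    tail so the anchored CD window closes exactly on the emitted span.
    Cysteines at offsets 41/63/83 (N-terminal subdomain, archetype census)
    plus one in the C-terminal subdomain; hatching adds the extra pair.
    """
    lo, hi = cfg.simhy_offset_window
    offset = int(rng.integers(lo, hi + 1))
    his1 = 95
    his3 = his1 + 10
    prefix = list(_bg(rng, 95))
    for p in (41, 63, 83):
        prefix[p] = "C"
    if hatching:
        for p in (50, 70):
            prefix[p] = "C"
    zinc = "HE" + _bg(rng, 2) + "H" + _bg(rng, 2) + "G" + _bg(rng, 2) + "H"
    fam_glu = "E"
    xxrxdrd = _bg(rng, 2) + "R" + _bg(rng, 1) + "DRD"
    # XXRXDRD ends at his3+9 (exclusive); SIMHY starts at his3+offset
    filler = _bg(rng, offset - 9)
    simhy = "SIMHY"
    tyr = his3 + offset + 4
    tail = list(_bg(rng, 59))
    tail[24] = "C"  # C-terminal-subdomain cysteine (offset tyr+25)
    seq = "".join(prefix) + zinc + fam_glu + xxrxdrd + filler + simhy + "".join(tail)
    anchors = {
        "his1": his1,
        "glu_cat": his1 + 1,
        "gly": his1 + 7,
        "his2": his1 + 4,
        "his3": his3,
        "family_glu": his3 + 1,
        "met_turn": his3 + offset + 2,
        "tyr_ligand": tyr,
    }
    assert len(seq) == tyr + 60
    return seq, anchors


def _egf_cassette(rng):
    """Canonical six-cysteine EGF framework (span 47, gaps 5/6/16/2/12)."""
    gaps = (5, 6, 16, 2, 12)
    parts = ["C"]
    for g in gaps:
        parts.append(_bg(rng, g) + "C")
    return "".join(parts)


def _shkt_cassette(rng):
    """ShKT toxin-like six-cysteine cassette (span 39, gaps 4/6/10/5/8)."""
    gaps = (4, 6, 10, 5, 8)
    parts = ["C"]
    for g in gaps:
        parts.append(_bg(rng, g) + "C")
    return "".join(parts)


_ARCHITECTURES = {
    "basic": (),
    "BTP": ("CUB", "CUB", "CUB", "EGF", "CUB", "EGF", "CUB"),
    "meprin_like": ("MAM", "TRAF", "EGF", "TM"),
    "hatching_like": ("CUB",),
    "shkt_astacin": ("ShKT",),
}
_DOMAIN_LEN = {"CUB": 110, "MAM": 170, "TRAF": 150}


def _downstream(subfamily: str, rng, start: int):
    """Build the downstream cassette string and its DomainHit list."""
    parts = []
    hits = []
    pos = start
    for name in _ARCHITECTURES[subfamily]:
        linker = _bg(rng, 5)
        parts.append(linker)
        pos += 5
        if name == "EGF":
            s = _egf_cassette(rng)
        elif name == "ShKT":
            s = _shkt_cassette(rng)
        elif name == "TM":
            s = _hydrophobic(rng, 23)
        else:
            s = _bg(rng, _DOMAIN_LEN[name])
        hits.append(DomainHit(name, pos, pos + len(s), source="provided"))
        parts.append(s)
        pos += len(s)
    return "".join(parts), tuple(hits)


def _sanitize(seq: str, truth: GroundTruth, rng) -> str:
    """Scramble accidental motif instances that would shadow the planted ones.

    Removes extra zinc-motif matches, extra SIMHY instances inside the search
    window, and extra FXGDI instances inside the prodomain, never touching a
    planted anchor or cysteine position.
    """
    protected = set(truth.anchors.values())
    a = truth.anchors
    if "his1" in a:
        protected.update(range(a["his3"] + 2, a["his3"] + 9))  # XXRXDRD span
        protected.update(range(a["met_turn"] - 2, a["met_turn"] + 3))  # SIMHY
    if "switch_asp" in a:
        protected.update(range(a["switch_asp"] - 3, a["switch_asp"] + 2))
    s = list(seq)
    for _ in range(20):
        changed = False
        text = "".join(s)
        if "his1" in a:
            for hit in scan_motif(text, ZINC_MOTIF):
                if hit.start == a["his1"]:
                    continue
                for off in (0, 1, 4, 10):
                    if hit.start + off not in protected:
                        s[hit.start + off] = "Q"
                        changed = True
                        break
            his3 = a["his3"]
            lo, hi = 20, 80
            for hit in scan_motif(text, SIMHY):
                if hit.start == a["met_turn"] - 2:
                    continue
                if lo <= hit.start - his3 <= hi:
                    for off in (2, 4):
                        if hit.start + off not in protected:
                            s[hit.start + off] = "Q"
                            changed = True
                            break
        p0, p1 = truth.pro_span
        if p1 > p0:
            planted = a["switch_asp"] - 3 if "switch_asp" in a else None
            for hit in scan_motif(text[p0:p1], FXGDI):
                start = hit.start + p0
                if start == planted:
                    continue
                for off in (3, 2):
                    if start + off not in protected:
                        s[start + off] = "Q"
                        changed = True
                        break
        if not changed:
            break
    return "".join(s)


def make_precursor(subfamily: str, cfg: GeneratorConfig, rng, record_id: str = "gen", clade: str | None = None):
    """Assemble one full precursor of the given subfamily with ground truth."""
    if subfamily not in SUBFAMILIES:
        raise ValueError(f"unknown subfamily {subfamily!r}")
    lo, hi = cfg.pro_length_bounds
    pro_len = int(rng.integers(lo, hi + 1))
    signal = "M" + _hydrophobic(rng, cfg.signal_length - 1)
    pro = _bg(rng, pro_len - 15) + "F" + _bg(rng, 1) + "GDI" + _bg(rng, 10)
    cd, cd_anchors = make_canonical_cd(cfg, rng, hatching=(subfamily == "hatching_like"))
    cd_start = cfg.signal_length + pro_len
    cd_end = cd_start + len(cd)
    down, hits = _downstream(subfamily, rng, cd_end)
    seq = signal + pro + cd + down
    anchors = {k: v + cd_start for k, v in cd_anchors.items()}
    anchors["switch_asp"] = cfg.signal_length + pro_len - 15 + 3
    truth = GroundTruth(
        anchors=anchors,
        cd_span=(cd_start, cd_end),
        pro_span=(cfg.signal_length, cd_start),
        domain_hits=hits,
        subfamily=subfamily,
    )
    seq = _sanitize(seq, truth, rng)
    return SequenceRecord(record_id, seq, clade=clade), truth


def _break_determinant(seq: str, truth: GroundTruth, decoy_class: str) -> str:
    a = truth.anchors
    s = list(seq)
    if decoy_class == "zinc_motif":
        s[a["his2"]] = "Q"
    elif decoy_class == "family_glu":
        s[a["family_glu"]] = "Q"
    elif decoy_class == "xxrxdrd":
        his3 = a["his3"]
        for off in (4, 6, 7, 8):  # the R/D/R/D anchors
            s[his3 + off] = "G"
    elif decoy_class == "simhy":
        s[a["met_turn"]] = "Q"
    else:
        raise ValueError(decoy_class)
    return "".join(s)


def make_decoys(n: int, cfg: GeneratorConfig, rng, prefix: str = "decoy"):
    """Generate *n* negative decoys, cycling classes per ``decoy_fractions``.

    Each decoy violates exactly one determinant and carries the reason code
    the validator must produce.
    """
    classes = sorted(cfg.decoy_fractions)
    counts = {c: int(round(cfg.decoy_fractions[c] * n)) for c in classes}
    # fix rounding so the total is exactly n
    while sum(counts.values()) > n:
        counts[max(classes, key=lambda c: counts[c])] -= 1
    while sum(counts.values()) < n:
        counts[min(classes, key=lambda c: counts[c])] += 1

    out = []
    k = 0
    for cls in classes:
        for _ in range(counts[cls]):
            rid = f"{prefix}_{cls}_{k}"
            k += 1
            if cls in ("zinc_motif", "family_glu", "xxrxdrd", "simhy"):
                rec, truth = make_precursor("basic", cfg, rng, record_id=rid)
                seq = _break_determinant(rec.sequence, truth, cls)
                rec = SequenceRecord(rid, seq)
            elif cls in ("pro_too_short", "pro_too_long"):
                pro_len = 33 if cls == "pro_too_short" else 500
                sub = GeneratorConfig(
                    pro_length_bounds=(pro_len, pro_len),
                    simhy_offset_window=cfg.simhy_offset_window,
                    signal_length=cfg.signal_length,
                )
                rec, truth = make_precursor("basic", sub, rng, record_id=rid)
            elif cls == "pro_missing":
                cd, cd_anchors = make_canonical_cd(cfg, rng)
                signal = "M" + _hydrophobic(rng, cfg.signal_length - 1)
                seq = signal + cd
                anchors = {k2: v + cfg.signal_length for k2, v in cd_anchors.items()}
                truth = GroundTruth(
                    anchors=anchors,
                    cd_span=(cfg.signal_length, cfg.signal_length + len(cd)),
                    pro_span=(cfg.signal_length, cfg.signal_length),
                    domain_hits=(),
                    subfamily="basic",
                )
                seq = _sanitize(seq, truth, rng)
                rec = SequenceRecord(rid, seq)
            else:  # no_latency_switch / cys_switch: motif-less prodomain
                lo, hi = cfg.pro_length_bounds
                pro_len = int(rng.integers(lo, hi + 1))
                signal = "M" + _hydrophobic(rng, cfg.signal_length - 1)
                pro = list(_bg(rng, pro_len))
                if cls == "cys_switch":
                    pro[pro_len // 2] = "C"
                cd, cd_anchors = make_canonical_cd(cfg, rng)
                cd_start = cfg.signal_length + pro_len
                seq = signal + "".join(pro) + cd
                anchors = {k2: v + cd_start for k2, v in cd_anchors.items()}
                truth = GroundTruth(
                    anchors=anchors,
                    cd_span=(cd_start, cd_start + len(cd)),
                    pro_span=(cfg.signal_length, cd_start),
                    domain_hits=(),
                    subfamily="basic",
                )
                seq = _sanitize(seq, truth, rng)
                clade = "Bacteria" if cls == "cys_switch" else None
                rec = SequenceRecord(rid, seq, clade=clade)
            truth.subfamily = "decoy"
            truth.decoy_class = cls
            truth.intended_reason = _DECOY_REASON[cls]
            out.append((rec, truth))
    return out


_METAZOAN_PHYLA = (
    "Chordata", "Hemichordata", "Echinodermata", "Tardigrada", "Arthropoda",
    "Nematoda", "Priapulida", "Bryozoa", "Brachiopoda", "Annelida",
    "Rotifera", "Mollusca", "Platyhelminthes", "Ctenophora", "Cnidaria",
    "Placozoa", "Porifera",
)


def make_cohort(cfg: GeneratorConfig, rng, n_decoys: int = 0):
    """A cohort of positives drawn from the subfamily mix, plus decoys."""
    subs = sorted(cfg.subfamily_mix)
    probs = np.array([cfg.subfamily_mix[s] for s in subs])
    out = []
    for i in range(cfg.n_taxa):
        sub = subs[int(rng.choice(len(subs), p=probs))]
        clade = str(rng.choice(_METAZOAN_PHYLA))
        rec, truth = make_precursor(sub, cfg, rng, record_id=f"ast_{i:04d}_{sub}", clade=clade)
        out.append((rec, truth))
    out.extend(make_decoys(n_decoys, cfg, rng))
    return out


def benchmark_panel(cfg: GeneratorConfig | None = None, rng=None, seed: int = 0):
    """The cross-phyla benchmark panel: 20 metazoan astacins spanning the
    animal phyla plus one bacterial cysteine-switch comparator."""
    cfg = cfg or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = []
    for rid, clade, sub in BENCHMARK_PANEL:
        rec, truth = make_precursor(sub, cfg, rng, record_id=rid, clade=clade)
        out.append((rec, truth))
    # the comparator reuses the cysteine-switch decoy construction
    rid, clade, _ = BENCHMARK_COMPARATOR
    sub_cfg = GeneratorConfig(decoy_fractions={"cys_switch": 1.0},
                              pro_length_bounds=cfg.pro_length_bounds,
                              signal_length=cfg.signal_length)
    (rec, truth), = make_decoys(1, sub_cfg, rng, prefix=rid)
    rec = SequenceRecord(rid, rec.sequence, clade=clade)
    out.append((rec, truth))
    return out


# --- evolution along a tree -------------------------------------------------


def _conservative_alternatives():
    m = blosum62()
    alts = {}
    for a in RESIDUES:
        alts[a] = [b for b in RESIDUES if b != a and m[(a, b)] > 0]
    return alts


def random_binary_tree(ids, rng, branch_length=1.0) -> PhyloTree:
    """A random rooted binary topology over *ids*.

    ``branch_length`` is either a constant or a callable drawing from rng.
    """
    draw = branch_length if callable(branch_length) else (lambda: branch_length)
    nodes = [TreeNode(name) for name in ids]
    for nd in nodes:
        nd.branch_length = float(draw())
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], branch_length=float(draw()))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return PhyloTree(root)


def evolve_along_tree(
    root_record: SequenceRecord,
    tree: PhyloTree,
    rate: float,
    rng,
    anchor_protection: bool = True,
    protected_positions=(),
):
    """Evolve a precursor along a tree by per-site substitutions.

    Per branch, each site substitutes with probability ``rate * length``
    (capped at 0.95). With anchor protection on, protected positions never
    mutate and substitutions are drawn uniformly from the conservative
    alternatives of the current residue (residues without any, such as Cys,
    stay fixed); with protection off, draws are uniform over all 19 other
    residues. Returns one SequenceRecord per leaf, named after the leaves.
    """
    alts = _conservative_alternatives() if anchor_protection else None
    protected = frozenset(protected_positions) if anchor_protection else frozenset()

    def mutate(seq: list, branch_length: float) -> list:
        p = min(rate * branch_length, 0.95)
        if p <= 0:
            return seq
        out = list(seq)
        hit = np.flatnonzero(rng.random(len(seq)) < p)
        for i in hit:
            if i in protected:
                continue
            cur = out[i]
            if anchor_protection:
                choices = alts.get(cur, [])
            else:
                choices = [r for r in RESIDUES if r != cur]
            if choices:
                out[i] = choices[int(rng.integers(len(choices)))]
        return out

    leaves = []

    def walk(node, seq):
        evolved = mutate(seq, node.branch_length)
        if node.is_leaf:
            leaves.append(
                SequenceRecord(node.name, "".join(evolved), taxon=root_record.taxon,
                               clade=root_record.clade)
            )
        for child in node.children:
            walk(child, evolved)

    root_seq = list(root_record.sequence.upper())
    for child in tree.root.children:
        walk(child, root_seq)
    return leaves


# --- cohort emission --------------------------------------------------------


def write_cohort(pairs, outdir, true_tree: PhyloTree | None = None) -> dict:
    """Write FASTA + metadata TSV + domain-hit TSV + ground-truth JSON (+ tree)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [rec for rec, _ in pairs]
    paths = {
        "fasta": outdir / "cohort.fasta",
        "metadata": outdir / "metadata.tsv",
        "domains": outdir / "domains.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_fasta(records, paths["fasta"])
    write_metadata_tsv(
        pd.DataFrame(
            {
                "id": [r.id for r in records],
                "taxon": [r.taxon or "" for r in records],
                "clade": [r.clade or "" for r in records],
            }
        ),
        paths["metadata"],
    )
    rows = []
    for rec, truth in pairs:
        for h in truth.domain_hits:
            rows.append({"id": rec.id, "domain": h.name, "start": h.start, "end": h.end})
    write_domain_hits_tsv(
        pd.DataFrame(rows, columns=["id", "domain", "start", "end"]), paths["domains"]
    )
    with open(paths["truth"], "w") as fh:
        json.dump({rec.id: truth.to_jsonable() for rec, truth in pairs}, fh, indent=1)
    if true_tree is not None:
        paths["tree"] = outdir / "true_tree.nwk"
        with open(paths["tree"], "w") as fh:
            fh.write(true_tree.to_newick() + "\n")
    return paths
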