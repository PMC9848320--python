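"""Residue-level motif grammar of the astacin catalytic domain.

Astacins (metzincin clan M12A zinc metallopeptidases) are defined at the
sequence level by a small set of determinants in the ~200-residue catalytic
domain (CD):

* the extended zinc-binding consensus ``HEXXHXXGXXH`` — three His zinc
  ligands plus the catalytic general base/acid Glu after the first His;
* a family-specific Glu immediately after the third zinc-binding His
  (position 103 in 1-based mature archetype numbering), which binds the
  mature N-terminus after activation;
* an ``XXRXDRD`` stretch of charged residues immediately after that Glu;
* a downstream ``SIMHY`` segment housing the Met-turn methionine and,
  two positions later, the Tyr zinc ligand;
* in the prodomain, the latency motif ``FXGDI`` whose Asp blocks the zinc.

This module expresses each determinant as a :class:`MotifSpec` — an ordered
list of wildcard and anchor positions — and scans sequences for matches,
allowing a bounded number of *conservative* substitutions (strictly positive
off-diagonal BLOSUM62 score) at the anchors marked substitutable. Zinc
ligands, the two glutamates, the Met-turn Met and the Tyr ligand are strictly
required by default; the peripheral letters of SIMHY/XXRXDRD/FXGDI and the
motif Gly may drift conservatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import AlphabetError, RESIDUE_SET, UNKNOWN, check_sequence
from .matrices import ScoreTable, blosum62

__all__ = [
    "Anchor",
    "MotifSpec",
    "MotifHit",
    "ZincSiteAnnotation",
    "ZincSiteRejection",
    "ScanConfig",
    "is_conservative",
    "scan_motif",
    "match_motif_at",
    "find_zinc_site",
    "ZINC_MOTIF",
    "XXRXDRD",
    "SIMHY",
    "FXGDI",
]


def is_conservative(a: str, b: str, matrix: ScoreTable | None = None) -> bool:
    """True iff *b* is a conservative replacement for *a*.

    Operationalised as a strictly positive off-diagonal substitution score;
    identity is not a substitution and returns False.
    """
    matrix = matrix if matrix is not None else blosum62()
    au, bu = a.upper(), b.upper()
    if au not in RESIDUE_SET or bu not in RESIDUE_SET:
        raise AlphabetError(f"not standard amino-acid letters: {a!r}, {b!r}")
    return au != bu and matrix[(au, bu)] > 0


@dataclass(frozen=True)
class Anchor:
    """One constrained motif position: an allowed residue set plus strictness."""

    label: str
    allowed: frozenset
    required: bool = True

    def __post_init__(self):
        if not self.allowed:
            raise ValueError(f"anchor {self.label!r} has an empty allowed set")
        bad = set(self.allowed) - RESIDUE_SET
        if bad:
            raise AlphabetError(f"anchor {self.label!r} allows non-residues {bad}")


@dataclass(frozen=True)
class MotifSpec:
    """An ordered motif pattern of wildcards (None) and :class:`Anchor` positions.

    ``max_conservative_subs`` budgets how many *substitutable* anchors may be
    satisfied by a conservative replacement instead of an exact match.
    """

    name: str
    positions: tuple
    max_conservative_subs: int = 2

    def __post_init__(self):
        if len(self.positions) < 1:
            raise ValueError("motif must have at least one position")
        if self.max_conservative_subs < 0:
            raise ValueError("substitution budget must be non-negative")
        for p in self.positions:
            if p is not None and not isinstance(p, Anchor):
                raise TypeError("positions must be Anchor or None (wildcard)")

    def __len__(self) -> int:
        return len(self.positions)

    def with_budget(self, budget: int) -> "MotifSpec":
        return MotifSpec(self.name, self.positions, budget)

    @classmethod
    def from_pattern(
        cls,
        name: str,
        pattern: str,
        max_conservative_subs: int = 2,
        labels: dict | None = None,
    ) -> "MotifSpec":
        """Build a spec from a compact pattern string.

        ``x`` or ``.`` is a wildcard; an UPPERCASE letter is a strictly
        required anchor; a lowercase letter is a substitutable anchor.
        ``labels`` optionally maps 0-based pattern offsets to anchor labels
        (default label: ``<letter><offset+1>``).
        """
        labels = labels or {}
        positions = []
        for i, c in enumerate(pattern):
            if c in ("x", "."):
                positions.append(None)
            else:
                residue = c.upper()
                if residue not in RESIDUE_SET:
                    raise AlphabetError(f"pattern letter {c!r} is not a residue")
                positions.append(
                    Anchor(
                        label=labels.get(i, f"{residue}{i + 1}"),
                        allowed=frozenset({residue}),
                        required=c.isupper(),
                    )
                )
        return cls(name, tuple(positions), max_conservative_subs)


@dataclass(frozen=True)
class MotifHit:
    """A located motif instance with substitution accounting.

    Offsets are 0-based on the scanned sequence; ``end`` is exclusive.
    ``anchor_positions`` maps anchor labels to absolute sequence offsets.
    """

    motif_name: str
    start: int
    end: int
    matched_subsequence: str
    n_substitutions: int
    substituted_positions: tuple
    anchor_positions: dict


# --- built-in astacin motif specs ------------------------------------------

ZINC_MOTIF = MotifSpec.from_pattern(
    "zinc_binding",
    "HExxHxxgxxH",
    labels={0: "his1", 1: "glu_cat", 4: "his2", 7: "gly", 10: "his3"},
)

XXRXDRD = MotifSpec.from_pattern(
    "xxrxdrd",
    "xxrxdrd",
    labels={2: "arg1", 4: "asp1", 5: "arg2", 6: "asp2"},
)

SIMHY = MotifSpec.from_pattern(
    "simhy",
    "siMhY",
    labels={0: "ser", 1: "ile", 2: "met_turn", 3: "his", 4: "tyr_ligand"},
)

FXGDI = MotifSpec.from_pattern(
    "fxgdi",
    "fxGDi",
    labels={0: "phe", 2: "gly", 3: "switch_asp", 4: "ile"},
)
# Note: the motif Gly of FXGDI is biologically conserved; it is kept required
# here while F and I may drift conservatively.  The switch Asp is required.


def match_motif_at(
    seq: str,
    pos: int,
    spec: MotifSpec,
    matrix: ScoreTable | None = None,
    *,
    _validated: bool = False,
) -> MotifHit | None:
    """Try to match *spec* at offset *pos*; return a hit or None.

    The sequence must already be upper-case/validated when ``_validated`` is
    set (used internally by :func:`scan_motif` to avoid re-validation).
    """
    if not _validated:
        seq = check_sequence(seq)
    matrix = matrix if matrix is not None else blosum62()
    L = len(spec)
    if pos < 0 or pos + L > len(seq):
        return None
    n_subs = 0
    subbed = []
    anchors = {}
    for i, anchor in enumerate(spec.positions):
        c = seq[pos + i]
        if anchor is None:
            continue  # wildcard: anything, including X
        if c in anchor.allowed:
            anchors[anchor.label] = pos + i
            continue
        if anchor.required or c == UNKNOWN:
            return None
        if any(matrix[(c, r)] > 0 for r in anchor.allowed):
            n_subs += 1
            subbed.append(pos + i)
            anchors[anchor.label] = pos + i
        else:
            return None
    if n_subs > spec.max_conservative_subs:
        return None
    return MotifHit(
        motif_name=spec.name,
        start=pos,
        end=pos + L,
        matched_subsequence=seq[pos : pos + L],
        n_substitutions=n_subs,
        substituted_positions=tuple(subbed),
        anchor_positions=anchors,
    )


def scan_motif(seq: str, spec: MotifSpec, matrix: ScoreTable | None = None) -> list:
    """All (possibly overlapping) matches of *spec* in *seq*, sorted by start."""
    s = check_sequence(seq)
    matrix = matrix if matrix is not None else blosum62()
    hits = []
    for pos in range(len(s) - len(spec) + 1):
        hit = match_motif_at(s, pos, spec, matrix, _validated=True)
        if hit is not None:
            hits.append(hit)
    return hits


# --- composed zinc-site search ---------------------------------------------


@dataclass(frozen=True)
class ScanConfig:
    """Configuration of the composed catalytic-site search.

    ``simhy_window`` bounds the distance (residues) from His3 to the start of
    the SIMHY segment; in the archetype the Met-turn sits roughly 45 residues
    past His3. Budgets default to 2 conservative substitutions per motif.
    """

    simhy_window: tuple = (20, 80)
    zinc_budget: int = 2
    xxrxdrd_budget: int = 2
    simhy_budget: int = 2
    fxgdi_budget: int = 2

    def zinc_spec(self) -> MotifSpec:
        return ZINC_MOTIF.with_budget(self.zinc_budget)

    def xxrxdrd_spec(self) -> MotifSpec:
        return XXRXDRD.with_budget(self.xxrxdrd_budget)

    def simhy_spec(self) -> MotifSpec:
        return SIMHY.with_budget(self.simhy_budget)

    def fxgdi_spec(self) -> MotifSpec:
        return FXGDI.with_budget(self.fxgdi_budget)


@dataclass(frozen=True)
class ZincSiteAnnotation:
    """The validated constellation of catalytic-domain anchors."""

    zinc_motif_hit: MotifHit
    family_glu_pos: int
    xxrxdrd_hit: MotifHit
    simhy_hit: MotifHit
    met_turn_pos: int
    tyr_ligand_pos: int

    @property
    def his1(self) -> int:
        return self.zinc_motif_hit.anchor_positions["his1"]

    @property
    def his2(self) -> int:
        return self.zinc_motif_hit.anchor_positions["his2"]

    @property
    def his3(self) -> int:
        return self.zinc_motif_hit.anchor_positions["his3"]

    @property
    def glu_cat(self) -> int:
        return self.zinc_motif_hit.anchor_positions["glu_cat"]

    @property
    def gly(self) -> int:
        return self.zinc_motif_hit.anchor_positions["gly"]

    def anchor_map(self) -> dict:
        """All seven CD anchors as label -> 0-based offset."""
        return {
            "his1": self.his1,
            "glu_cat": self.glu_cat,
            "gly": self.gly,
            "his2": self.his2,
            "his3": self.his3,
            "family_glu": self.family_glu_pos,
            "met_turn": self.met_turn_pos,
            "tyr_ligand": self.tyr_ligand_pos,
        }


@dataclass(frozen=True)
class ZincSiteRejection:
    """Machine-readable record of why no consistent zinc site was found."""

    reason_codes: tuple

    def __bool__(self) -> bool:  # a rejection is falsy; an annotation truthy
        return False


def find_zinc_site(seq: str, cfg: ScanConfig | None = None):
    """Locate the first internally consistent astacin catalytic constellation.

    Composition: the zinc-binding motif; the family-specific Glu exactly at
    His3+1; XXRXDRD starting at His3+2; SIMHY starting within
    ``cfg.simhy_window`` residues downstream of His3 (nearest instance taken).
    Returns a :class:`ZincSiteAnnotation`, or a :class:`ZincSiteRejection`
    listing every failed criterion of the best (first) zinc-motif candidate.
    """
    cfg = cfg or ScanConfig()
    s = check_sequence(seq)
    matrix = blosum62()
    zinc_hits = scan_motif(s, cfg.zinc_spec(), matrix)
    if not zinc_hits:
        return ZincSiteRejection(("zinc_motif_missing",))

    first_reasons = None
    simhy_spec = cfg.simhy_spec()
    lo, hi = cfg.simhy_window
    for zh in zinc_hits:
        reasons = []
        his3 = zh.anchor_positions["his3"]
        family_glu = his3 + 1
        if family_glu >= len(s) or s[family_glu] != "E":
            reasons.append("family_glu_missing")
        xh = match_motif_at(s, his3 + 2, cfg.xxrxdrd_spec(), matrix, _validated=True)
        if xh is None:
            reasons.append("xxrxdrd_missing")
        sh = None
        for start in range(his3 + lo, min(his3 + hi, len(s) - len(simhy_spec)) + 1):
            sh = match_motif_at(s, start, simhy_spec, matrix, _validated=True)
            if sh is not None:
                break
        if sh is None:
            reasons.append("simhy_missing")
        if not reasons:
            return ZincSiteAnnotation(
                zinc_motif_hit=zh,
                family_glu_pos=family_glu,
                xxrxdrd_hit=xh,
                simhy_hit=sh,
                met_turn_pos=sh.anchor_positions["met_turn"],
                tyr_ligand_pos=sh.anchor_positions["tyr_ligand"],
            )
        if first_reasons is None:
            first_reasons = tuple(reasons)
    return ZincSiteRejection(first_reasons)
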