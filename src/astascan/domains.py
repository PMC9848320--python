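"""Subfamily classification from downstream domain architecture.

Beyond the minimal signal + prodomain + CD core, astacin subfamilies are
distinguished by the domains appended C-terminal of the CD:

* BTPs (BMP1/Tolloid-like): five CUB plus two EGF-like domains;
* meprins: MAM + TRAF (+ EGF-like, transmembrane anchor);
* hatching enzymes: an extra Cys pair in the CD's N-terminal subdomain,
  optionally with extra CUB domains;
* ShKT-astacins: one or more six-cysteine toxin-like ShKT cassettes;
* "basic" astacins: the bare S-PRO-CD archetype.

Profile-level detection of CUB/MAM/TRAF is delegated to external tools and
supplied as a hit table; only the small cysteine-framework cassettes (EGF,
ShKT) have lightweight built-in pattern scanners here. Classification then
applies a fixed, configurable precedence over the downstream architecture.
"""

from __future__ import annotations

from dataclasses import dataclass

from .zymogen import CatalyticDomainAnnotation

__all__ = [
    "DomainHit",
    "ArchitectureCall",
    "CONTROLLED_VOCAB",
    "SUBFAMILY_LABELS",
    "scan_simple_domains",
    "classify_subfamily",
]

CONTROLLED_VOCAB = frozenset({"CUB", "EGF", "MAM", "TRAF", "ShKT", "TM"})
SUBFAMILY_LABELS = (
    "meprin_like",
    "BTP",
    "hatching_like",
    "shkt_astacin",
    "basic",
    "unclassified",
)

# Inter-cysteine gap classes (residues strictly between consecutive Cys) of
# the canonical six-cysteine EGF framework, and overall span windows.
_EGF_GAPS = ((3, 14), (3, 7), (1, 16), (1, 2), (8, 23))
_EGF_SPAN = (35, 50)
_SHKT_SPAN = (28, 45)


@dataclass(frozen=True)
class DomainHit:
    """A located downstream domain (0-based half-open coordinates)."""

    name: str
    start: int
    end: int
    source: str = "provided"  # provided | pattern

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"domain hit {self.name!r}: start must precede end")


@dataclass(frozen=True)
class ArchitectureCall:
    """Ordered downstream architecture plus the subfamily verdict."""

    ordered_domains: tuple
    subfamily: str
    shkt_flag: bool
    membrane_flag: bool
    unknown_domains: tuple = ()


def _egf_gaps_ok(cys6) -> bool:
    for (lo, hi), a, b in zip(_EGF_GAPS, cys6, cys6[1:]):
        if not (lo <= b - a - 1 <= hi):
            return False
    return True


def scan_simple_domains(seq: str) -> list:
    """Built-in scanners for the EGF and ShKT six-cysteine cassettes.

    A sextet of consecutive cysteines is called EGF when its span and all
    five inter-cysteine gaps fall in the canonical classes; otherwise it is
    called ShKT when its span fits the tighter ShKT window. Matching is
    greedy left-to-right and hits never share a cysteine, so hits are
    non-overlapping per domain type. EGF takes priority on ambiguity.
    """
    s = seq.upper()
    cys = [i for i, c in enumerate(s) if c == "C"]
    hits: list[DomainHit] = []
    i = 0
    while i + 6 <= len(cys):
        six = cys[i : i + 6]
        span = six[5] - six[0] + 1
        if _EGF_SPAN[0] <= span <= _EGF_SPAN[1] and _egf_gaps_ok(six):
            hits.append(DomainHit("EGF", six[0], six[5] + 1, source="pattern"))
            i += 6
        elif _SHKT_SPAN[0] <= span <= _SHKT_SPAN[1] and not _egf_gaps_ok(six):
            hits.append(DomainHit("ShKT", six[0], six[5] + 1, source="pattern"))
            i += 6
        else:
            i += 1
    return hits


def classify_subfamily(
    cd: CatalyticDomainAnnotation,
    hits,
    hatching_cys: bool,
    *,
    mam_only_meprin: bool = False,
    precedence=("meprin_like", "BTP", "hatching_like", "shkt_astacin"),
) -> ArchitectureCall:
    """Assign the subfamily label from the downstream architecture.

    Only hits starting at or after the CD end contribute to the ordered
    architecture. Default precedence (most specific signature first):
    meprin (MAM and TRAF both present) > BTP (at least three CUB) >
    hatching (extra CD Cys pair with at most two CUB) > ShKT-astacin
    (any ShKT) > basic (no downstream domains) > unclassified. Unknown
    domain names pass through into the architecture, never fatal.
    """
    downstream = sorted(
        (h for h in hits if h.start >= cd.cd_end), key=lambda h: (h.start, h.end, h.name)
    )
    names = tuple(h.name for h in downstream)
    unknown = tuple(sorted({n for n in names if n not in CONTROLLED_VOCAB}))
    n_cub = sum(1 for n in names if n == "CUB")
    has_shkt = any(n == "ShKT" for n in names)

    def rule(label: str) -> bool:
        if label == "meprin_like":
            has_mam = "MAM" in names
            return has_mam and ("TRAF" in names or mam_only_meprin)
        if label == "BTP":
            return n_cub >= 3
        if label == "hatching_like":
            return hatching_cys and n_cub <= 2
        if label == "shkt_astacin":
            return has_shkt
        raise ValueError(f"unknown precedence label {label!r}")

    subfamily = "unclassified"
    for label in precedence:
        if rule(label):
            subfamily = label
            break
    else:
        if not names:
            subfamily = "basic"

    return ArchitectureCall(
        ordered_domains=names,
        subfamily=subfamily,
        shkt_flag=has_shkt,
        membrane_flag="TM" in names,
        unknown_domains=unknown,
    )
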