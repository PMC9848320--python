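"""Catalytic-domain delimitation, latency-switch annotation and curation.

A candidate astacin precursor is accepted only if it carries the complete
determinant constellation — intact zinc-binding motif, family-specific Glu,
XXRXDRD and SIMHY motifs with at most minimal conservative substitutions — a
catalytic domain of plausible length, and a prodomain with the zinc-blocking
aspartate of the FXGDI latency motif. Failures are reported as machine-
readable reason codes, never exceptions.

The CD is delimited from its anchors: it starts ``n_up`` residues before the
first zinc-binding His and ends ``c_down`` residues after the Tyr zinc
ligand. The defaults (95 and 60) reproduce the archetypal ~200-residue
crayfish domain from its anchor constellation; the window check (170-260
residues) guards against truncated or runaway spans. The N-terminal
subdomain ends at the motif Gly, where the chain turns into the C-terminal
subdomain; cysteines are censused on each side because hatching-enzyme-like
astacins carry an extra Cys pair in the N-terminal subdomain.

Latency: animal astacin prodomains carry FXGDI whose Asp blocks the zinc
("aspartate switch"); some bacterial xenologues instead use a prodomain Cys
("cysteine switch") and lack the motif. Only the aspartate switch satisfies
the curation criteria; cysteine-switch forms are flagged as xenologue
candidates, as are records whose clade metadata falls outside Holozoa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import check_sequence
from .io import SequenceRecord
from .motifs import (
    MotifHit,
    ScanConfig,
    ZincSiteAnnotation,
    ZincSiteRejection,
    find_zinc_site,
    match_motif_at,
    scan_motif,
)
from .taxonomy import DEFAULT_TAXONOMY, CladeTaxonomy

__all__ = [
    "ValidatorConfig",
    "CatalyticDomainAnnotation",
    "ZymogenAnnotation",
    "ValidationReport",
    "NoProdomainError",
    "REASON_CODES",
    "annotate_cd",
    "annotate_zymogen",
    "validate_astacin",
    "classify_hatching_cys",
]

REASON_CODES = frozenset(
    {
        "zinc_motif_missing",
        "family_glu_missing",
        "xxrxdrd_missing",
        "simhy_missing",
        "cd_truncated",
        "cd_length_out_of_window",
        "pro_missing",
        "pro_too_short",
        "pro_too_long",
        "no_latency_switch",
    }
)


class NoProdomainError(ValueError):
    """Raised when zymogen annotation is requested for a mature-only sequence."""


@dataclass(frozen=True)
class ValidatorConfig:
    """Tunable curation parameters.

    n_up / c_down: CD boundary offsets from His1 / the Tyr ligand (residues).
    cd_length_window: accepted CD lengths; the family's domains span ~200.
    pro_length_bounds: accepted prodomain lengths (34-486 across the family).
    signal_end: 0-based offset where the prodomain starts (signal peptides
    are not predicted here; supply the annotated signal length if known).
    archetype_n_subdomain_cys: N-terminal-subdomain cysteine count of the
    archetype (3: the C42/C64/C84 side of its two disulfides).
    """

    scan: ScanConfig = field(default_factory=ScanConfig)
    n_up: int = 95
    c_down: int = 60
    cd_length_window: tuple = (170, 260)
    pro_length_bounds: tuple = (34, 486)
    signal_end: int = 0
    archetype_n_subdomain_cys: int = 3
    taxonomy: CladeTaxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)


@dataclass(frozen=True)
class CatalyticDomainAnnotation:
    """The delimited CD span, its anchors and its cysteine census."""

    cd_start: int
    cd_end: int
    zinc_site: ZincSiteAnnotation
    cys_positions: tuple
    n_subdomain_cys_extra: int
    truncated: bool

    @property
    def cd_length(self) -> int:
        return self.cd_end - self.cd_start

    @property
    def n_potential_disulfides(self) -> int:
        return len(self.cys_positions) // 2


@dataclass(frozen=True)
class ZymogenAnnotation:
    """Prodomain span and latency-switch call."""

    pro_start: int
    pro_end: int
    fxgdi_hit: MotifHit | None
    switch_type: str  # aspartate | cysteine | none
    switch_pos: int | None

    @property
    def pro_length(self) -> int:
        return self.pro_end - self.pro_start

    @property
    def activation_site(self) -> int:
        return self.pro_end


@dataclass(frozen=True)
class ValidationReport:
    """Per-record curation outcome with reason codes."""

    id: str
    accepted: bool
    cd: CatalyticDomainAnnotation | None
    zymogen: ZymogenAnnotation | None
    reason_codes: tuple
    xenologue_flag: bool


def annotate_cd(
    seq: str, site: ZincSiteAnnotation, cfg: ValidatorConfig | None = None
) -> CatalyticDomainAnnotation:
    """Delimit the CD around the anchor constellation and census cysteines."""
    cfg = cfg or ValidatorConfig()
    s = check_sequence(seq)
    raw_start = site.his1 - cfg.n_up
    raw_end = site.tyr_ligand_pos + cfg.c_down
    cd_start = max(0, raw_start)
    cd_end = min(len(s), raw_end)
    truncated = raw_start < 0 or raw_end > len(s)
    cys = tuple(i for i in range(cd_start, cd_end) if s[i] == "C")
    # N-terminal subdomain: everything before the motif Gly turn
    n_sub_cys = sum(1 for i in cys if i < site.gly)
    extra = max(0, n_sub_cys - cfg.archetype_n_subdomain_cys)
    return CatalyticDomainAnnotation(
        cd_start=cd_start,
        cd_end=cd_end,
        zinc_site=site,
        cys_positions=cys,
        n_subdomain_cys_extra=extra,
        truncated=truncated,
    )


def annotate_zymogen(
    seq: str, cd: CatalyticDomainAnnotation, cfg: ValidatorConfig | None = None
) -> ZymogenAnnotation:
    """Annotate the prodomain upstream of the CD and type its latency switch.

    The FXGDI motif is searched within the prodomain; when several instances
    occur the one nearest the activation site is taken. An aspartate switch
    requires the motif's Asp; a cysteine switch is called for a motif-less
    prodomain containing at least one Cys (the bacterial pattern).
    """
    cfg = cfg or ValidatorConfig()
    s = check_sequence(seq)
    pro_start = cfg.signal_end
    pro_end = cd.cd_start
    if pro_end <= pro_start:
        raise NoProdomainError("no prodomain upstream of the catalytic domain")
    pro = s[pro_start:pro_end]
    spec = cfg.scan.fxgdi_spec()
    hits = scan_motif(pro, spec)
    fxgdi = None
    if hits:
        h = hits[-1]  # nearest to the activation site
        fxgdi = MotifHit(
            motif_name=h.motif_name,
            start=h.start + pro_start,
            end=h.end + pro_start,
            matched_subsequence=h.matched_subsequence,
            n_substitutions=h.n_substitutions,
            substituted_positions=tuple(p + pro_start for p in h.substituted_positions),
            anchor_positions={k: v + pro_start for k, v in h.anchor_positions.items()},
        )
    if fxgdi is not None:
        switch_type = "aspartate"
        switch_pos = fxgdi.anchor_positions["switch_asp"]
    else:
        cys = [i for i in range(pro_start, pro_end) if s[i] == "C"]
        if cys:
            switch_type = "cysteine"
            switch_pos = cys[0]
        else:
            switch_type = "none"
            switch_pos = None
    return ZymogenAnnotation(
        pro_start=pro_start,
        pro_end=pro_end,
        fxgdi_hit=fxgdi,
        switch_type=switch_type,
        switch_pos=switch_pos,
    )


def classify_hatching_cys(
    cd: CatalyticDomainAnnotation, cfg: ValidatorConfig | None = None
) -> bool:
    """True iff the N-terminal subdomain carries at least one extra Cys pair."""
    return cd.n_subdomain_cys_extra >= 2


def validate_astacin(
    record: SequenceRecord, cfg: ValidatorConfig | None = None
) -> ValidationReport:
    """Full curation of one precursor record; deterministic given (record, cfg)."""
    cfg = cfg or ValidatorConfig()
    reasons: list[str] = []
    cd = None
    zym = None

    site = find_zinc_site(record.sequence, cfg.scan)
    if isinstance(site, ZincSiteRejection):
        reasons.extend(site.reason_codes)
    else:
        cd = annotate_cd(record.sequence, site, cfg)
        if cd.truncated:
            reasons.append("cd_truncated")
        lo, hi = cfg.cd_length_window
        if not (lo <= cd.cd_length <= hi):
            reasons.append("cd_length_out_of_window")
        if cd.cd_start <= cfg.signal_end:
            reasons.append("pro_missing")
        else:
            zym = annotate_zymogen(record.sequence, cd, cfg)
            plo, phi = cfg.pro_length_bounds
            if zym.pro_length < plo:
                reasons.append("pro_too_short")
            elif zym.pro_length > phi:
                reasons.append("pro_too_long")
            if zym.switch_type != "aspartate":
                reasons.append("no_latency_switch")

    xenologue = False
    if record.clade:
        xenologue = not cfg.taxonomy.is_holozoan(record.clade)
    if zym is not None and zym.switch_type == "cysteine":
        xenologue = True

    return ValidationReport(
        id=record.id,
        accepted=not reasons,
        cd=cd,
        zymogen=zym,
        reason_codes=tuple(reasons),
        xenologue_flag=xenologue,
    )
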