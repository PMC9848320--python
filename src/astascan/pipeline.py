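"""End-to-end orchestration: scan -> validate -> classify -> align -> tree.

The pipeline consumes a precursor FASTA (plus optional per-sequence metadata
and externally produced domain-hit tables), curates each record, classifies
accepted astacins by downstream architecture, and builds a bootstrapped
neighbor-joining tree of the accepted catalytic domains with a per-clade
presence/absence summary. All outputs are plain text (JSON lines, TSV,
aligned FASTA, PHYLIP, Newick) and every coordinate written to disk is
1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .domains import DomainHit, classify_subfamily, scan_simple_domains
from .io import (
    SequenceRecord,
    read_domain_hits_tsv,
    read_fasta,
    read_metadata_tsv,
    write_fasta,
    write_jsonl,
    write_phylip,
)
from .motifs import ScanConfig
from .phylo import Alignment, bootstrap_tree, distance_matrix, progressive_msa, summarize_clades
from .zymogen import ValidatorConfig, classify_hatching_cys, validate_astacin

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report_to_dict"]

logger = logging.getLogger("astascan")

STATUS_OK = "ok"
STATUS_NO_ASTACINS = "no_astacins"


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs plus input/output paths; YAML round-trippable."""

    input_fasta: str = ""
    metadata_tsv: str | None = None
    domains_tsv: str | None = None
    outdir: str = "astascan_out"
    validator: ValidatorConfig = field(default_factory=ValidatorConfig)
    gap_open: float = 10.0
    gap_extend: float = 0.5
    correction: str = "kimura"
    bootstrap_reps: int = 100
    seed: int = 0
    mam_only_meprin: bool = False
    precedence: tuple = ("meprin_like", "BTP", "hatching_like", "shkt_astacin")
    build_tree: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["validator"].pop("taxonomy", None)  # static fixture, not configurable
        d["precedence"] = list(self.precedence)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        v = dict(d.pop("validator", {}))
        scan = ScanConfig(**{k: tuple(x) if isinstance(x, list) else x
                             for k, x in dict(v.pop("scan", {})).items()})
        for key in ("cd_length_window", "pro_length_bounds"):
            if key in v and isinstance(v[key], list):
                v[key] = tuple(v[key])
        validator = ValidatorConfig(scan=scan, **v)
        if "precedence" in d:
            d["precedence"] = tuple(d["precedence"])
        return cls(validator=validator, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    status: str
    reports: list
    architectures: dict
    tree: object | None
    alignment: Alignment | None
    clade_summary: pd.DataFrame | None
    paths: dict


def _one_based(span) -> list:
    return [span[0] + 1, span[1]]


def report_to_dict(report, arch=None) -> dict:
    """Serialise a ValidationReport (+ArchitectureCall) with 1-based coordinates."""
    out = {
        "id": report.id,
        "accepted": report.accepted,
        "reason_codes": list(report.reason_codes),
        "xenologue_flag": report.xenologue_flag,
        "coordinate_system": "1-based inclusive",
    }
    if report.cd is not None:
        site = report.cd.zinc_site
        out["cd"] = {
            "span": _one_based((report.cd.cd_start, report.cd.cd_end)),
            "length": report.cd.cd_length,
            "n_cysteines": len(report.cd.cys_positions),
            "n_potential_disulfides": report.cd.n_potential_disulfides,
            "n_subdomain_cys_extra": report.cd.n_subdomain_cys_extra,
            "anchors": {k: v + 1 for k, v in site.anchor_map().items()},
        }
    if report.zymogen is not None:
        z = report.zymogen
        out["zymogen"] = {
            "pro_span": _one_based((z.pro_start, z.pro_end)),
            "pro_length": z.pro_length,
            "switch_type": z.switch_type,
            "switch_pos": None if z.switch_pos is None else z.switch_pos + 1,
            "activation_site": z.activation_site + 1,
        }
    if arch is not None:
        out["architecture"] = {
            "ordered_domains": list(arch.ordered_domains),
            "subfamily": arch.subfamily,
            "shkt_flag": arch.shkt_flag,
            "membrane_flag": arch.membrane_flag,
        }
    return out


def _load_inputs(config: RunConfig):
    records = read_fasta(config.input_fasta)
    if config.metadata_tsv:
        meta = read_metadata_tsv(config.metadata_tsv)
        by_id = {row.id: row for row in meta.itertuples()}
        records = [
            r.with_metadata(
                taxon=getattr(by_id.get(r.id), "taxon", None) or None,
                clade=getattr(by_id.get(r.id), "clade", None) or None,
            )
            for r in records
        ]
    provided: dict = {}
    if config.domains_tsv:
        df = read_domain_hits_tsv(config.domains_tsv)
        for row in df.itertuples():
            provided.setdefault(row.id, []).append(
                DomainHit(row.domain, int(row.start), int(row.end), source="provided")
            )
    return records, provided


def _merge_hits(provided, scanned):
    """Provided hits win over overlapping pattern hits of the same domain."""
    merged = list(provided)
    for h in scanned:
        clash = any(
            p.name == h.name and p.start < h.end and h.start < p.end for p in provided
        )
        if not clash:
            merged.append(h)
    return merged


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run configuration: %s", config.to_dict())

    records, provided = _load_inputs(config)
    reports = []
    architectures = {}
    accepted: list[SequenceRecord] = []
    cd_records: list[SequenceRecord] = []
    rows = []
    for rec in records:
        report = validate_astacin(rec, config.validator)
        reports.append(report)
        arch = None
        if report.accepted:
            hits = _merge_hits(provided.get(rec.id, []), scan_simple_domains(rec.sequence))
            arch = classify_subfamily(
                report.cd,
                hits,
                classify_hatching_cys(report.cd, config.validator),
                mam_only_meprin=config.mam_only_meprin,
                precedence=config.precedence,
            )
            architectures[rec.id] = arch
            accepted.append(rec)
            cd_records.append(
                SequenceRecord(rec.id, rec.sequence[report.cd.cd_start : report.cd.cd_end])
            )
        rows.append(
            {
                "id": rec.id,
                "accepted": report.accepted,
                "subfamily": arch.subfamily if arch else "",
                "reason_codes": ";".join(report.reason_codes),
                "xenologue_flag": report.xenologue_flag,
                "clade": rec.clade or "",
            }
        )

    paths = {
        "report": outdir / "report.jsonl",
        "summary": outdir / "summary.tsv",
    }
    write_jsonl(
        (report_to_dict(r, architectures.get(r.id)) for r in reports), paths["report"]
    )
    pd.DataFrame(rows).to_csv(paths["summary"], sep="\t", index=False)

    if not accepted:
        logger.info("no astacins found; stopping after validation")
        return PipelineResult(STATUS_NO_ASTACINS, reports, architectures, None, None, None, paths)

    paths["cd_fasta"] = outdir / "accepted_cds.fasta"
    write_fasta(cd_records, paths["cd_fasta"])

    tree = None
    aln = None
    summary = None
    if config.build_tree and len(cd_records) >= 2:
        aln = progressive_msa(cd_records, gap_open=config.gap_open, gap_extend=config.gap_extend)
        paths["alignment"] = outdir / "alignment.fasta"
        write_fasta(
            [SequenceRecord(i, r) for i, r in zip(aln.ids, aln.rows)], paths["alignment"]
        )
        dm = distance_matrix(aln, correction=config.correction)
        paths["distances"] = outdir / "distances.phylip"
        write_phylip(dm.ids, dm.values, paths["distances"])
        tree = bootstrap_tree(
            aln, n_reps=config.bootstrap_reps, seed=config.seed, correction=config.correction
        )
        paths["tree"] = outdir / "tree.nwk"
        with open(paths["tree"], "w") as fh:
            fh.write(tree.to_newick() + "\n")
        clades = {r.id: (r.clade or "") for r in accepted}
        summary = summarize_clades(tree, clades)
        paths["clade_summary"] = outdir / "clade_summary.tsv"
        summary.to_csv(paths["clade_summary"], sep="\t", index=False)

    return PipelineResult(STATUS_OK, reports, architectures, tree, aln, summary, paths)
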