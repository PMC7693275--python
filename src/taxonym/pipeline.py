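"""Batch name resolution: ordered result tables and CSV serialization."""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import HybridNotationError, NameParseError
from .matching import MatchConfig, MatchResult, resolve_single
from .parser import parse
from .reference import ACCEPTED, ReferenceTable

logger = logging.getLogger(__name__)

__all__ = ["ResolutionRow", "ResultTable", "resolve_names", "write_results", "read_results"]

#: CSV column order; stable public schema.
CSV_COLUMNS = (
    "Submitted_Name",
    "Matched_Name",
    "Status",
    "Accepted_Taxon",
    "Order",
    "Family",
    "Genus",
    "Epithet",
    "Rank",
    "Infraspecies",
    "Authority",
    "Dist_Genus",
    "Dist_Epithet",
    "Dist_Infra",
    "Dist_Authority",
    "Total_Distance",
    "Score",
    "Ambiguous",
)


@dataclass
class ResolutionRow:
    """One output row; unresolved rows are empty except for the
    submitted name and the score."""

    submitted_name: str
    matched_name: str = ""
    status: str = ""
    accepted_taxon: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    epithet: str = ""
    rank: str = ""
    infraspecies: str = ""
    authority: str = ""
    dist_genus: int | None = None
    dist_epithet: int | None = None
    dist_infra: int | None = None
    dist_authority: int | None = None
    total_distance: int | None = None
    score: str = ""
    ambiguous: bool | None = None

    @property
    def matched(self) -> bool:
        return bool(self.matched_name)

    def to_csv_values(self) -> list[str]:
        def cell(v):
            if v is None:
                return ""
            if isinstance(v, bool):
                return "true" if v else "false"
            return str(v)

        return [cell(getattr(self, f.name)) for f in fields(self)]

    @classmethod
    def from_csv_values(cls, values: list[str]) -> "ResolutionRow":
        kwargs = {}
        for f, v in zip(fields(cls), values):
            if f.name.startswith("dist_") or f.name == "total_distance":
                kwargs[f.name] = int(v) if v != "" else None
            elif f.name == "ambiguous":
                kwargs[f.name] = None if v == "" else v == "true"
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


@dataclass
class ResultTable:
    """Ordered batch-resolution output, >= one row per submitted name."""

    rows: list[ResolutionRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def _parse_failure_score(exc: Exception, raw: str) -> str:
    if isinstance(exc, HybridNotationError):
        return "hybrid sign not accepted"
    if not (raw or "").strip():
        return "empty input"
    return "epithet missing"


def _row_for_candidate(raw: str, result: MatchResult, candidate) -> ResolutionRow:
    rec = candidate.record
    p = rec.parsed
    comps = {c.component: c for c in candidate.components.values()}
    dist = {n: (comps[n].distance if n in comps else None) for n in ("genus", "epithet", "infra", "authority")}
    accepted_taxon = rec.input_name if rec.status == ACCEPTED else rec.accepted_name
    score = "|".join(
        candidate.components[n].describe()
        for n in ("genus", "epithet", "infra", "authority")
        if n in candidate.components
    )
    return ResolutionRow(
        submitted_name=raw,
        matched_name=rec.input_name,
        status=rec.status,
        accepted_taxon=accepted_taxon,
        order=rec.order,
        family=rec.family,
        genus=p.genus + ("_x" if p.genus_hybrid else ""),
        epithet=p.epithet + ("_x" if p.epithet_hybrid else ""),
        rank=p.rank_marker,
        infraspecies=p.infra_epithet,
        authority=p.authority,
        dist_genus=dist["genus"],
        dist_epithet=dist["epithet"],
        dist_infra=dist["infra"],
        dist_authority=dist["authority"],
        total_distance=candidate.total_distance,
        score=score,
        ambiguous=result.ambiguous,
    )


def resolve_names(
    queries: list[str], table: ReferenceTable, cfg: MatchConfig | None = None
) -> ResultTable:
    """Resolve a batch of raw name strings, preserving submission order.

    Per-query parse failures become unresolved rows with an explanatory
    score; they never abort the batch.
    """
    cfg = cfg or MatchConfig()
    if len(queries) > cfg.batch_warn_threshold:
        logger.warning(
            "%d names submitted; batches above %d may be slow — consider "
            "splitting the input",
            len(queries),
            cfg.batch_warn_threshold,
        )
    out = ResultTable()
    for raw in queries:
        try:
            p = parse(raw)
        except NameParseError as exc:
            out.rows.append(
                ResolutionRow(submitted_name=raw, score=_parse_failure_score(exc, raw))
            )
            continue
        result = resolve_single(p, table, cfg)
        if not result.matched:
            out.rows.append(
                ResolutionRow(submitted_name=raw, score=result.score)
            )
            continue
        if cfg.return_all_ties and len(result.ties) > 1:
            for cand in result.ties:
                out.rows.append(_row_for_candidate(raw, result, cand))
        else:
            out.rows.append(_row_for_candidate(raw, result, result.ties[0]))
    return out


def write_results(rt: ResultTable, path) -> None:
    """Write *rt* as an RFC-4180-style UTF-8 CSV (header + one line per row).

    *path* may be a filesystem path or an open text file object.
    """
    if hasattr(path, "write"):
        _write_csv(rt, path)
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_csv(rt, fh)


def _write_csv(rt: ResultTable, fh) -> None:
    writer = csv.writer(fh, lineterminator="\r\n")
    writer.writerow(CSV_COLUMNS)
    for row in rt.rows:
        writer.writerow(row.to_csv_values())


def results_to_csv_text(rt: ResultTable) -> str:
    buf = io.StringIO()
    _write_csv(rt, buf)
    return buf.getvalue()


def read_results(path: str | Path) -> ResultTable:
    """Read back a CSV written by :func:`write_results`."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != CSV_COLUMNS:
            raise ValueError(f"unexpected result header: {header!r}")
        return ResultTable(rows=[ResolutionRow.from_csv_values(r) for r in reader])
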