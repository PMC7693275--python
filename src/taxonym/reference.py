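"""Loading, validation, flattening, summary and diff of reference backbones.

A backbone is a tab-delimited UTF-8 table, one published name per row,
carrying the name's status (accepted / synonym / unresolved) and, for
synonyms, a cross-reference to the accepted name.  Column headers and
the status vocabulary vary between file versions, so both are described
by a :class:`Dialect` that maps them onto the internal schema.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import parser as _parser
from .distance import edit_distance_at_most
from .errors import ReferenceFormatError, StatusMappingError, SynonymCycleError

logger = logging.getLogger(__name__)

__all__ = [
    "ACCEPTED",
    "SYNONYM",
    "UNRESOLVED",
    "Dialect",
    "DEFAULT_DIALECT",
    "IDIV_DIALECT",
    "ReferenceRecord",
    "ReferenceTable",
    "ValidationReport",
    "SummaryStats",
    "DiffOptions",
    "DiffReport",
    "load_reference",
    "write_reference",
    "validate_reference",
    "flatten_synonym_chains",
    "summarize",
    "diff_backbones",
]

ACCEPTED = "accepted"
SYNONYM = "synonym"
UNRESOLVED = "unresolved"
_STATUSES = (ACCEPTED, SYNONYM, UNRESOLVED)

_STATUS_PRIORITY = {ACCEPTED: 0, SYNONYM: 1, UNRESOLVED: 2}


@dataclass(frozen=True)
class Dialect:
    """Mapping from file columns / vocabulary onto the internal schema.

    ``columns`` maps internal field names (``input_name``, ``status``,
    ``accepted_name``, and optionally ``family``, ``order``,
    ``tpl_comparison``) to file column headers.  ``status_map`` maps
    file status values (compared case-insensitively) to the status enum.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {
            "input_name": "Input_Taxon",
            "status": "Status",
            "accepted_name": "Output_Taxon",
            "family": "Family",
            "order": "Order",
            "tpl_comparison": "TPL_Comparison",
        }
    )
    status_map: dict[str, str] = field(
        default_factory=lambda: {
            "accepted": ACCEPTED,
            "synonym": SYNONYM,
            "unresolved": UNRESOLVED,
        }
    )
    name: str = "default"

    def __post_init__(self):
        required = {"input_name", "status", "accepted_name"}
        missing = required - set(self.columns)
        if missing:
            raise ReferenceFormatError(
                f"dialect {self.name!r} lacks column mapping(s): {sorted(missing)}"
            )
        bad = set(self.status_map.values()) - set(_STATUSES)
        if bad:
            raise ReferenceFormatError(
                f"dialect {self.name!r} maps onto unknown status(es): {sorted(bad)}"
            )

    def map_status(self, value: str) -> str | None:
        return self.status_map.get(value.strip().casefold())

    def file_status(self, status: str) -> str:
        """First file vocabulary value mapping to *status* (for writing)."""
        for k, v in self.status_map.items():
            if v == status:
                return k
        return status

    @classmethod
    def from_config(cls, path: str | Path) -> "Dialect":
        """Read a dialect from a plain ``key = value`` config file.

        Keys ``column.<field>`` define column mappings and
        ``status.<file value>`` define status vocabulary entries; lines
        starting with ``#`` are comments.
        """
        columns: dict[str, str] = {}
        status_map: dict[str, str] = {}
        for lineno, line in enumerate(
            Path(path).read_text("utf-8").splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ReferenceFormatError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}"
                )
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("column."):
                columns[key[len("column."):]] = value
            elif key.startswith("status."):
                status_map[key[len("status."):].casefold()] = value.casefold()
            else:
                raise ReferenceFormatError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(columns=columns, status_map=status_map, name=str(path))


DEFAULT_DIALECT = Dialect()

#: Dialect for the archived catalogue distribution (dotted headers as
#: used by the iDiv data portal export).
IDIV_DIALECT = Dialect(
    columns={
        "input_name": "Input.Taxon",
        "status": "Status",
        "accepted_name": "Output.Taxon",
        "family": "Family",
        "order": "Order",
        "tpl_comparison": "PL.comparison",
    },
    status_map={
        "accepted": ACCEPTED,
        "valid": ACCEPTED,
        "synonym": SYNONYM,
        "invalid": SYNONYM,
        "unresolved": UNRESOLVED,
        "blank": UNRESOLVED,
        "": UNRESOLVED,
    },
    name="idiv",
)

DIALECTS = {"default": DEFAULT_DIALECT, "idiv": IDIV_DIALECT}


@dataclass
class ReferenceRecord:
    """One backbone row: a published name, its status, its cross-reference."""

    input_name: str
    status: str
    accepted_name: str = ""
    family: str = ""
    order: str = ""
    tpl_comparison: str = ""
    parsed: _parser.ParsedName | None = None
    extras: dict[str, str] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if self.status not in _STATUSES:
            raise ReferenceFormatError(
                f"record {self.input_name!r} has invalid status {self.status!r}"
            )
        if self.parsed is None:
            self.parsed = _parser.parse(self.input_name)

    @property
    def genus(self) -> str:
        return self.parsed.genus


def _canonical_or_stripped(name: str) -> str:
    name = " ".join((name or "").split())
    if not name:
        return ""
    try:
        return _parser.parse(name).canonical()
    except _parser.NameParseError:
        return name


def make_record(
    input_name: str,
    status: str,
    accepted_name: str = "",
    *,
    family: str = "",
    order: str = "",
    tpl_comparison: str = "",
    extras: dict[str, str] | None = None,
) -> ReferenceRecord:
    """Build a record, canonicalizing both name strings."""
    parsed = _parser.parse(input_name)
    return ReferenceRecord(
        input_name=parsed.canonical(),
        status=status,
        accepted_name=_canonical_or_stripped(accepted_name),
        family=family,
        order=order,
        tpl_comparison=tpl_comparison,
        parsed=parsed,
        extras=extras or {},
    )


class ReferenceTable:
    """Ordered collection of :class:`ReferenceRecord` with lookup indexes."""

    def __init__(self, records: list[ReferenceRecord], provenance: str = ""):
        self.records: list[ReferenceRecord] = list(records)
        self.provenance = provenance
        self.genus_index: dict[str, list[ReferenceRecord]] = {}
        self.name_index: dict[str, ReferenceRecord] = {}
        self.rebuild_indexes()

    def rebuild_indexes(self) -> None:
        self.genus_index = {}
        self.name_index = {}
        for rec in self.records:
            self.genus_index.setdefault(rec.genus, []).append(rec)
            # first occurrence wins; duplicates are a validation finding
            self.name_index.setdefault(rec.input_name, rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lookup(self, input_name: str) -> ReferenceRecord | None:
        return self.name_index.get(input_name)


@dataclass
class ValidationReport:
    """Structural findings for one backbone table."""

    n_records: int = 0
    dangling_synonyms: list[str] = field(default_factory=list)
    chained_synonyms: list[list[str]] = field(default_factory=list)
    cycles: list[list[str]] = field(default_factory=list)
    duplicate_names: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not (
            self.dangling_synonyms
            or self.chained_synonyms
            or self.cycles
            or self.duplicate_names
        )

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "valid": self.is_valid,
            "dangling_synonyms": list(self.dangling_synonyms),
            "chained_synonyms": [list(c) for c in self.chained_synonyms],
            "cycles": [list(c) for c in self.cycles],
            "duplicate_names": list(self.duplicate_names),
        }


@dataclass
class SummaryStats:
    """Content counts for one backbone table.

    The partition is: every record is exactly one of accepted
    non-hybrid (species or infraspecific), accepted hybrid, synonym, or
    unresolved, so ``total_names == accepted_incl_infraspecific +
    natural_hybrids + synonyms + unresolved``.
    """

    total_names: int = 0
    accepted_species: int = 0
    accepted_incl_infraspecific: int = 0
    accepted_infraspecific: int = 0
    natural_hybrids: int = 0
    synonyms: int = 0
    unresolved: int = 0
    genera_accepted: int = 0
    genera_all: int = 0
    families: int = 0
    orders: int = 0
    unresolved_by_genus: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["unresolved_by_genus"] = {
            g: {"unresolved": u, "total": t}
            for g, (u, t) in sorted(self.unresolved_by_genus.items())
        }
        return d


def load_reference(
    path: str | Path, dialect: Dialect | None = None
) -> ReferenceTable:
    """Load a backbone table from a tab-delimited UTF-8 file.

    Every row becomes a :class:`ReferenceRecord` with parsed name
    components; row order is preserved and unmapped columns are kept in
    ``record.extras``.

    Raises
    ------
    ReferenceFormatError
        If a mapped column is missing from the file.
    StatusMappingError
        If the file uses status values the dialect does not map.
    """
    dialect = dialect or DEFAULT_DIALECT
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    colmap = dialect.columns
    for fieldname in ("input_name", "status", "accepted_name"):
        if colmap[fieldname] not in df.columns:
            raise ReferenceFormatError(
                f"{path}: required column {colmap[fieldname]!r} "
                f"(mapped to {fieldname!r}) is missing"
            )
    mapped_cols = {c for f, c in colmap.items() if c in df.columns}
    extra_cols = [c for c in df.columns if c not in mapped_cols]

    bad_statuses = sorted(
        {v for v in df[colmap["status"]] if dialect.map_status(v) is None}
    )
    if bad_statuses:
        raise StatusMappingError(bad_statuses)

    def col(row, fieldname):
        c = colmap.get(fieldname)
        return row[c] if c in df.columns else ""

    records = []
    for row in df.to_dict("records"):
        records.append(
            make_record(
                input_name=row[colmap["input_name"]],
                status=dialect.map_status(row[colmap["status"]]),
                accepted_name=row[colmap["accepted_name"]],
                family=col(row, "family"),
                order=col(row, "order"),
                tpl_comparison=col(row, "tpl_comparison"),
                extras={c: row[c] for c in extra_cols},
            )
        )
    return ReferenceTable(records, provenance=str(path))


def write_reference(
    table: ReferenceTable, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write *table* as a tab-delimited UTF-8 file in *dialect*."""
    dialect = dialect or DEFAULT_DIALECT
    colmap = dialect.columns
    rows = []
    for rec in table.records:
        row = {
            colmap["input_name"]: rec.input_name,
            colmap["status"]: dialect.file_status(rec.status),
            colmap["accepted_name"]: rec.accepted_name,
        }
        for fieldname in ("family", "order", "tpl_comparison"):
            if fieldname in colmap:
                row[colmap[fieldname]] = getattr(rec, fieldname)
        row.update(rec.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def _chain_from(rec: ReferenceRecord, table: ReferenceTable) -> tuple[list[str], str]:
    """Follow synonym cross-references from *rec*.

    Returns the visited name path and a terminal kind: ``accepted``,
    ``unresolved``, ``dangling`` or ``cycle``.
    """
    path = [rec.input_name]
    seen = {rec.input_name}
    current = rec
    while True:
        target_name = current.accepted_name
        if not target_name:
            return path, "dangling"
        target = table.lookup(target_name)
        if target is None:
            path.append(target_name)
            return path, "dangling"
        path.append(target.input_name)
        if target.status == ACCEPTED:
            return path, ACCEPTED
        if target.status == UNRESOLVED:
            return path, UNRESOLVED
        if target.input_name in seen:
            return path, "cycle"
        seen.add(target.input_name)
        current = target


def validate_reference(table: ReferenceTable) -> ValidationReport:
    """Report dangling cross-references, chains, cycles and duplicates.

    Pure function: the table is left untouched and problems are
    reported, never raised.
    """
    report = ValidationReport(n_records=len(table))

    counts = Counter(rec.input_name for rec in table)
    report.duplicate_names = sorted(n for n, c in counts.items() if c > 1)

    seen_cycles: set[frozenset[str]] = set()
    for rec in table:
        if rec.status != SYNONYM:
            continue
        path, terminal = _chain_from(rec, table)
        if terminal == "dangling":
            report.dangling_synonyms.append(rec.input_name)
        elif terminal == "cycle":
            cycle_members = frozenset(path[:-1])
            if cycle_members not in seen_cycles:
                seen_cycles.add(cycle_members)
                report.cycles.append(sorted(cycle_members))
        else:
            direct = table.lookup(rec.accepted_name)
            if direct is not None and direct.status == SYNONYM:
                report.chained_synonyms.append(path)
    return report


def flatten_synonym_chains(table: ReferenceTable) -> ReferenceTable:
    """Rewrite every synonym cross-reference to its terminal accepted name.

    Synonyms whose chain dead-ends (missing or unresolved target) are
    demoted to unresolved with a logged warning.  Idempotent; records
    are copied, the input table is not modified.

    Raises
    ------
    SynonymCycleError
        If the synonym cross-references contain a cycle.
    """
    cycles = validate_reference(table).cycles
    if cycles:
        raise SynonymCycleError(cycles)

    new_records = []
    for rec in table:
        if rec.status != SYNONYM:
            new_records.append(dataclasses.replace(rec))
            continue
        path, terminal = _chain_from(rec, table)
        if terminal == ACCEPTED:
            new_records.append(dataclasses.replace(rec, accepted_name=path[-1]))
        else:
            logger.warning(
                "synonym %r has no accepted terminal (chain %s ends %s); "
                "demoted to unresolved",
                rec.input_name,
                " -> ".join(path),
                terminal,
            )
            new_records.append(
                dataclasses.replace(rec, status=UNRESOLVED, accepted_name="")
            )
    return ReferenceTable(new_records, provenance=table.provenance)


def summarize(table: ReferenceTable) -> SummaryStats:
    """Count the information content of *table*.

    Hybrids are accepted records whose parsed name carries a hybrid
    flag; ``accepted_species`` counts species-rank non-hybrid accepted
    names; families/orders/accepted genera are counted over accepted
    records only.
    """
    stats = SummaryStats(total_names=len(table))
    genera_accepted: set[str] = set()
    genera_all: set[str] = set()
    families: set[str] = set()
    orders: set[str] = set()
    by_genus_total: Counter = Counter()
    by_genus_unresolved: Counter = Counter()

    for rec in table:
        p = rec.parsed
        genera_all.add(p.genus)
        by_genus_total[p.genus] += 1
        if rec.status == ACCEPTED:
            genera_accepted.add(p.genus)
            if rec.family:
                families.add(rec.family)
            if rec.order:
                orders.add(rec.order)
            if p.is_hybrid:
                stats.natural_hybrids += 1
            elif p.is_infraspecific:
                stats.accepted_infraspecific += 1
                stats.accepted_incl_infraspecific += 1
            else:
                stats.accepted_species += 1
                stats.accepted_incl_infraspecific += 1
        elif rec.status == SYNONYM:
            stats.synonyms += 1
        else:
            stats.unresolved += 1
            by_genus_unresolved[p.genus] += 1

    stats.genera_accepted = len(genera_accepted)
    stats.genera_all = len(genera_all)
    stats.families = len(families)
    stats.orders = len(orders)
    stats.unresolved_by_genus = {
        g: (by_genus_unresolved[g], by_genus_total[g]) for g in by_genus_unresolved
    }
    return stats


@dataclass(frozen=True)
class DiffOptions:
    """Tuning knobs for :func:`diff_backbones`.

    Two names absent from each other's table but agreeing on authority,
    rank and hybrid flags are classified as orthographic variants when
    their combined genus+epithet(+infra) edit distance lies in
    ``[min_orthography_distance, max_orthography_distance]``.
    """

    min_orthography_distance: int = 1
    max_orthography_distance: int = 3


@dataclass
class DiffReport:
    """Comparison of two backbone tables.

    Names are paired across tables by their authority-free canonical
    form.  Every name in the union falls in exactly one presence class:
    paired (further classified as identical / different_author /
    different_synonym / other_difference) or only_in_a / only_in_b.
    Status contrasts are counted over paired names only and are not
    exclusive of the record classification.  ``different_orthography``
    is an overlay count over the only_in_* leftovers.
    """

    identical: int = 0
    only_in_a: int = 0
    only_in_b: int = 0
    different_author: int = 0
    different_synonym: int = 0
    different_orthography: int = 0
    other_difference: int = 0
    resolved_in_a_unresolved_in_b: int = 0
    accepted_in_a_synonym_in_b: int = 0
    synonym_in_a_accepted_in_b: int = 0
    names: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["names"] = {k: list(v) for k, v in self.names.items()}
        return d


def _pair_by_key(
    recs_a: list[ReferenceRecord], recs_b: list[ReferenceRecord]
) -> tuple[list[tuple], list[ReferenceRecord], list[ReferenceRecord]]:
    """Pair records sharing a name key, preferring equal authorities."""
    by_auth_b = {}
    for rec in recs_b:
        by_auth_b.setdefault(rec.parsed.authority, []).append(rec)
    pairs = []
    rest_a = []
    for rec in recs_a:
        bucket = by_auth_b.get(rec.parsed.authority)
        if bucket:
            pairs.append((rec, bucket.pop(0)))
        else:
            rest_a.append(rec)
    rest_b = [r for bucket in by_auth_b.values() for r in bucket]
    rest_a.sort(key=lambda r: r.input_name)
    rest_b.sort(key=lambda r: r.input_name)
    n = min(len(rest_a), len(rest_b))
    pairs.extend(zip(rest_a[:n], rest_b[:n]))
    return pairs, rest_a[n:], rest_b[n:]


def diff_backbones(
    a: ReferenceTable, b: ReferenceTable, options: DiffOptions | None = None
) -> DiffReport:
    """Compare two backbone tables record by record."""
    options = options or DiffOptions()
    report = DiffReport()
    names: dict[str, list] = {
        "identical": [],
        "only_in_a": [],
        "only_in_b": [],
        "different_author": [],
        "different_synonym": [],
        "different_orthography": [],
        "other_difference": [],
        "resolved_in_a_unresolved_in_b": [],
        "accepted_in_a_synonym_in_b": [],
        "synonym_in_a_accepted_in_b": [],
    }
    report.names = names

    keyed_a: dict[tuple, list[ReferenceRecord]] = {}
    keyed_b: dict[tuple, list[ReferenceRecord]] = {}
    for rec in a:
        keyed_a.setdefault(rec.parsed.name_key(), []).append(rec)
    for rec in b:
        keyed_b.setdefault(rec.parsed.name_key(), []).append(rec)

    lonely_a: list[ReferenceRecord] = []
    lonely_b: list[ReferenceRecord] = []
    for key in keyed_a:
        if key in keyed_b:
            pairs, rest_a, rest_b = _pair_by_key(keyed_a[key], keyed_b[key])
            lonely_a.extend(rest_a)
            lonely_b.extend(rest_b)
            for ra, rb in pairs:
                _classify_pair(ra, rb, report, names)
        else:
            lonely_a.extend(keyed_a[key])
    for key in keyed_b:
        if key not in keyed_a:
            lonely_b.extend(keyed_b[key])

    report.only_in_a = len(lonely_a)
    report.only_in_b = len(lonely_b)
    names["only_in_a"] = sorted(r.input_name for r in lonely_a)
    names["only_in_b"] = sorted(r.input_name for r in lonely_b)

    _overlay_orthography(lonely_a, lonely_b, options, report, names)
    return report


def _classify_pair(ra, rb, report: DiffReport, names: dict) -> None:
    pa, pb = ra.parsed, rb.parsed
    if pa.authority != pb.authority:
        report.different_author += 1
        names["different_author"].append((ra.input_name, rb.input_name))
    elif (
        ra.status == SYNONYM
        and rb.status == SYNONYM
        and ra.accepted_name != rb.accepted_name
    ):
        report.different_synonym += 1
        names["different_synonym"].append(ra.input_name)
    elif ra.status == rb.status and ra.accepted_name == rb.accepted_name:
        report.identical += 1
        names["identical"].append(ra.input_name)
    else:
        report.other_difference += 1
        names["other_difference"].append(ra.input_name)

    if ra.status != UNRESOLVED and rb.status == UNRESOLVED:
        report.resolved_in_a_unresolved_in_b += 1
        names["resolved_in_a_unresolved_in_b"].append(ra.input_name)
    if ra.status == ACCEPTED and rb.status == SYNONYM:
        report.accepted_in_a_synonym_in_b += 1
        names["accepted_in_a_synonym_in_b"].append(ra.input_name)
    if ra.status == SYNONYM and rb.status == ACCEPTED:
        report.synonym_in_a_accepted_in_b += 1
        names["synonym_in_a_accepted_in_b"].append(ra.input_name)


def _overlay_orthography(
    lonely_a, lonely_b, options: DiffOptions, report: DiffReport, names: dict
) -> None:
    lo, hi = options.min_orthography_distance, options.max_orthography_distance
    taken: set[int] = set()
    for ra in sorted(lonely_a, key=lambda r: r.input_name):
        pa = ra.parsed
        for idx, rb in enumerate(sorted(lonely_b, key=lambda r: r.input_name)):
            if idx in taken:
                continue
            pb = rb.parsed
            if (
                pa.authority != pb.authority
                or pa.rank_marker != pb.rank_marker
                or pa.genus_hybrid != pb.genus_hybrid
                or pa.epithet_hybrid != pb.epithet_hybrid
            ):
                continue
            budget = hi
            dg = edit_distance_at_most(pa.genus, pb.genus, budget)
            if dg is None:
                continue
            de = edit_distance_at_most(pa.epithet, pb.epithet, budget - dg)
            if de is None:
                continue
            di = edit_distance_at_most(
                pa.infra_epithet, pb.infra_epithet, budget - dg - de
            )
            if di is None:
                continue
            total = dg + de + di
            if lo <= total <= hi:
                report.different_orthography += 1
                names["different_orthography"].append(
                    (ra.input_name, rb.input_name)
                )
                taken.add(idx)
                break
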