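"""Staged fuzzy resolution of a parsed name against a reference table.

Resolution proceeds genus first, then epithet, then infraspecific
epithet and authority (each only when supplied), with a per-component
budget of letters allowed to disagree (Levenshtein distance).  At every
stage an exact hit preempts all fuzzy candidates, so a verbatim name can
never be shadowed by a typo-match.  Failure is a value — an empty match
whose score string says which component could not be matched — never an
exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .distance import edit_distance, edit_distance_at_most
from .parser import ParsedName
from .reference import ReferenceRecord, ReferenceTable, _STATUS_PRIORITY

__all__ = [
    "MatchConfig",
    "ComponentMatch",
    "MatchResult",
    "Candidate",
    "edit_distance",
    "match_genus",
    "match_epithet",
    "rank_candidates",
    "resolve_single",
]

EXACT = "exact"
FUZZY = "fuzzy"
UNMATCHED = "unmatched"
NOT_SUPPLIED = "not_supplied"

_COMPONENT_ORDER = ("genus", "epithet", "infra", "authority")

# interchangeable rank spellings treated as the same rank level
_RANK_CANON = {"ssp.": "subsp.", "forma": "f."}


@dataclass(frozen=True)
class MatchConfig:
    """Thresholds and switches for fuzzy resolution.

    Distances are the maximum number of letters allowed to disagree per
    component.  ``fuzzy_authority`` enables fuzzy (rather than equality)
    comparison of supplied authorities; an authority mismatch never
    vetoes a candidate, it is only reported in the score and used to
    break ties.
    """

    max_distance_genus: int = 2
    max_distance_epithet: int = 2
    max_distance_infra: int = 2
    max_distance_authority: int = 2
    fuzzy_authority: bool = False
    return_all_ties: bool = False
    batch_warn_threshold: int = 5000

    def __post_init__(self):
        for name in (
            "max_distance_genus",
            "max_distance_epithet",
            "max_distance_infra",
            "max_distance_authority",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_warn_threshold <= 0:
            raise ValueError("batch_warn_threshold must be > 0")


@dataclass(frozen=True)
class ComponentMatch:
    """Outcome of matching one name component.

    ``distance`` is ``None`` unless the state is exact or fuzzy.
    """

    component: str
    submitted: str = ""
    matched: str = ""
    distance: int | None = None
    state: str = UNMATCHED

    def describe(self) -> str:
        if self.state == FUZZY:
            return f"{self.component}:fuzzy({self.distance})"
        return f"{self.component}:{self.state}"


@dataclass
class Candidate:
    """A reference record with per-component match outcomes."""

    record: ReferenceRecord
    components: dict[str, ComponentMatch] = field(default_factory=dict)

    @property
    def total_distance(self) -> int:
        return sum(
            c.distance
            for c in self.components.values()
            if c.state in (EXACT, FUZZY)
        )

    @property
    def authority_penalty(self) -> int:
        auth = self.components.get("authority")
        return 1 if auth is not None and auth.state == UNMATCHED else 0

    def sort_key(self) -> tuple:
        return (
            self.total_distance,
            self.authority_penalty,
            _STATUS_PRIORITY[self.record.status],
            self.record.input_name,
        )


@dataclass
class MatchResult:
    """Outcome of resolving one parsed name.

    ``record`` is ``None`` when resolution failed; the ``score`` string
    then says which component could not be matched.  ``ties`` carries
    the equally-ranked candidates when ``return_all_ties`` is active.
    """

    record: ReferenceRecord | None
    components: list[ComponentMatch]
    total_distance: int = 0
    ambiguous: bool = False
    ties: list[Candidate] = field(default_factory=list)

    @property
    def matched(self) -> bool:
        return self.record is not None

    @property
    def score(self) -> str:
        return "|".join(c.describe() for c in self.components)


def _hybrid_token(base: str, hybrid: bool) -> str:
    return base + "_x" if hybrid else base


def match_genus(
    genus: str, table: ReferenceTable, cfg: MatchConfig
) -> dict[str, int]:
    """All reference genera within the genus threshold, with distances.

    An exact hit preempts: if *genus* itself occurs in the table, only
    the distance-0 entry is returned.
    """
    if genus in table.genus_index:
        return {genus: 0}
    out: dict[str, int] = {}
    for candidate in table.genus_index:
        d = edit_distance_at_most(genus, candidate, cfg.max_distance_genus)
        if d is not None:
            out[candidate] = d
    return out


def _genus_component(p: ParsedName, rec: ReferenceRecord, genus_dist: int) -> ComponentMatch | None:
    rp = rec.parsed
    d = genus_dist + (p.genus_hybrid != rp.genus_hybrid)
    sub = _hybrid_token(p.genus, p.genus_hybrid)
    mat = _hybrid_token(rp.genus, rp.genus_hybrid)
    return ComponentMatch("genus", sub, mat, d, EXACT if d == 0 else FUZZY)


def match_epithet(
    genus_candidates: dict[str, int],
    p: ParsedName,
    table: ReferenceTable,
    cfg: MatchConfig,
) -> list[Candidate]:
    """Candidate records within the epithet threshold in candidate genera.

    Hybrid-flag disagreement on genus or epithet costs one extra letter
    of the respective budget.  Distance-0 epithet hits preempt fuzzy
    ones.
    """
    cands: list[Candidate] = []
    sub_epi = _hybrid_token(p.epithet, p.epithet_hybrid)
    for genus, gdist in genus_candidates.items():
        for rec in table.genus_index.get(genus, ()):
            rp = rec.parsed
            gcomp = _genus_component(p, rec, gdist)
            if gcomp.distance > cfg.max_distance_genus:
                continue
            flag_pen = int(p.epithet_hybrid != rp.epithet_hybrid)
            d = edit_distance_at_most(
                p.epithet, rp.epithet, cfg.max_distance_epithet - flag_pen
            )
            if d is None:
                continue
            ed = d + flag_pen
            ecomp = ComponentMatch(
                "epithet",
                sub_epi,
                _hybrid_token(rp.epithet, rp.epithet_hybrid),
                ed,
                EXACT if ed == 0 else FUZZY,
            )
            cands.append(Candidate(rec, {"genus": gcomp, "epithet": ecomp}))
    return _preempt(cands, "epithet")


def _preempt(cands: list[Candidate], component: str) -> list[Candidate]:
    if any(c.components[component].distance == 0 for c in cands):
        return [c for c in cands if c.components[component].distance == 0]
    return cands


def _rank_compatible(a: str, b: str) -> bool:
    return _RANK_CANON.get(a, a) == _RANK_CANON.get(b, b)


def _apply_infra_stage(
    cands: list[Candidate], p: ParsedName, cfg: MatchConfig
) -> list[Candidate]:
    """Filter candidates by infraspecific level / epithet."""
    kept: list[Candidate] = []
    if p.rank_marker:
        for c in cands:
            rp = c.record.parsed
            if not rp.rank_marker or not _rank_compatible(
                p.rank_marker, rp.rank_marker
            ):
                continue
            d = edit_distance_at_most(
                p.infra_epithet, rp.infra_epithet, cfg.max_distance_infra
            )
            if d is None:
                continue
            c.components["infra"] = ComponentMatch(
                "infra",
                p.infra_epithet,
                rp.infra_epithet,
                d,
                EXACT if d == 0 else FUZZY,
            )
            kept.append(c)
        return _preempt(kept, "infra")
    # no infraspecific part supplied: resolve at species level only
    for c in cands:
        if not c.record.parsed.rank_marker:
            c.components["infra"] = ComponentMatch("infra", state=NOT_SUPPLIED)
            kept.append(c)
    return kept


def _apply_authority_stage(
    cands: list[Candidate], p: ParsedName, cfg: MatchConfig
) -> None:
    for c in cands:
        ref_auth = c.record.parsed.authority
        if not p.authority:
            c.components["authority"] = ComponentMatch(
                "authority", state=NOT_SUPPLIED
            )
            continue
        if cfg.fuzzy_authority:
            d = edit_distance_at_most(
                p.authority, ref_auth, cfg.max_distance_authority
            )
        else:
            d = 0 if p.authority == ref_auth else None
        if d is None:
            c.components["authority"] = ComponentMatch(
                "authority", p.authority, ref_auth, None, UNMATCHED
            )
        else:
            c.components["authority"] = ComponentMatch(
                "authority", p.authority, ref_auth, d, EXACT if d == 0 else FUZZY
            )


def rank_candidates(
    cands: list[Candidate], p: ParsedName, cfg: MatchConfig
) -> tuple[list[Candidate], bool]:
    """Order candidates and flag ambiguity.

    Order: total distance, then unmatched-authority penalty, then
    status priority (accepted before synonym before unresolved), then
    canonical name.  The result is ambiguous when at least two
    candidates tie on everything but the name.
    """
    ranked = sorted(cands, key=Candidate.sort_key)
    ambiguous = (
        len(ranked) >= 2 and ranked[0].sort_key()[:3] == ranked[1].sort_key()[:3]
    )
    return ranked, ambiguous


def _failure(components: dict[str, ComponentMatch], p: ParsedName) -> MatchResult:
    comps = []
    for name in _COMPONENT_ORDER:
        if name in components:
            comps.append(components[name])
            continue
        supplied = {
            "genus": True,
            "epithet": True,
            "infra": bool(p.rank_marker),
            "authority": bool(p.authority),
        }[name]
        comps.append(
            ComponentMatch(name, state=UNMATCHED if supplied else NOT_SUPPLIED)
        )
    total = sum(c.distance for c in comps if c.state in (EXACT, FUZZY))
    return MatchResult(record=None, components=comps, total_distance=total)


def _best_genus_component(
    genus_candidates: dict[str, int], p: ParsedName
) -> ComponentMatch:
    best = min(genus_candidates.items(), key=lambda kv: (kv[1], kv[0]))
    name, d = best
    return ComponentMatch(
        "genus",
        _hybrid_token(p.genus, p.genus_hybrid),
        name,
        d,
        EXACT if d == 0 else FUZZY,
    )


def resolve_single(
    p: ParsedName, table: ReferenceTable, cfg: MatchConfig | None = None
) -> MatchResult:
    """Resolve one parsed name against a (flattened) reference table.

    Stages: genus, epithet, infraspecific name and authority (the last
    two only when supplied).  Deterministic for a given (name, table,
    config) regardless of table row order.
    """
    cfg = cfg or MatchConfig()

    genus_candidates = match_genus(p.genus, table, cfg)
    if not genus_candidates:
        return _failure(
            {"genus": ComponentMatch("genus", p.genus, state=UNMATCHED)}, p
        )

    cands = match_epithet(genus_candidates, p, table, cfg)
    if not cands:
        return _failure(
            {
                "genus": _best_genus_component(genus_candidates, p),
                "epithet": ComponentMatch(
                    "epithet",
                    _hybrid_token(p.epithet, p.epithet_hybrid),
                    state=UNMATCHED,
                ),
            },
            p,
        )

    survivors = _apply_infra_stage(cands, p, cfg)
    if not survivors:
        best = min(cands, key=Candidate.sort_key)
        return _failure(
            {
                "genus": best.components["genus"],
                "epithet": best.components["epithet"],
                "infra": ComponentMatch(
                    "infra", p.infra_epithet, state=UNMATCHED
                ),
            },
            p,
        )

    _apply_authority_stage(survivors, p, cfg)
    ranked, ambiguous = rank_candidates(survivors, p, cfg)
    best = ranked[0]
    components = [best.components[name] for name in _COMPONENT_ORDER]
    n_ties = 1
    if cfg.return_all_ties:
        key = best.sort_key()[:3]
        n_ties = sum(1 for c in ranked if c.sort_key()[:3] == key)
    return MatchResult(
        record=best.record,
        components=components,
        total_distance=best.total_distance,
        ambiguous=ambiguous,
        ties=ranked[:n_ties],
    )
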