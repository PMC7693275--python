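"""Shared test helpers: tiny-table builders and independent oracles.

The oracles re-derive expected behaviour from first principles (full
DP matrix, exhaustive scans, pointer chasing) and deliberately share no
code with the package's optimized paths.
"""

from __future__ import annotations

from taxonym.reference import ReferenceTable, make_record

STATUS_RANK = {"accepted": 0, "synonym": 1, "unresolved": 2}


def mk_table(rows, provenance="test"):
    """Build a ReferenceTable from (name, status[, accepted_name]) tuples."""
    records = []
    for row in rows:
        name, status = row[0], row[1]
        accepted = row[2] if len(row) > 2 else (name if status == "accepted" else "")
        records.append(make_record(name, status, accepted))
    return ReferenceTable(records, provenance=provenance)


def oracle_levenshtein(a: str, b: str) -> int:
    """Full-matrix Levenshtein DP, the reference for edit_distance."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][0] = i
    for j in range(m + 1):
        dp[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i][j] = min(
                dp[i - 1][j] + 1,
                dp[i][j - 1] + 1,
                dp[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return dp[n][m]


def _rank_canon(r: str) -> str:
    return {"ssp.": "subsp.", "forma": "f."}.get(r, r)


def _tok(base: str, hybrid: bool) -> str:
    return base + "_x" if hybrid else base


def oracle_resolve(p, table, cfg):
    """Exhaustive staged matcher over every record of *table*.

    Returns ``(matched_input_name_or_None, total_distance, ambiguous)``
    applying, stage by stage, the documented rules: per-component
    thresholds, exact-hit preemption, hybrid-flag penalty of one,
    species-level restriction when no infraspecific part is supplied,
    authority equality (non-vetoing), and the ordering key
    (total distance, authority-unmatched penalty, status priority,
    canonical name).
    """
    lev = oracle_levenshtein

    genus_d = {}
    for rec in table:
        g = rec.parsed.genus
        if g not in genus_d:
            genus_d[g] = lev(p.genus, g)
    within = {g: d for g, d in genus_d.items() if d <= cfg.max_distance_genus}
    if not within:
        return None, 0, False
    if 0 in within.values():
        within = {g: d for g, d in within.items() if d == 0}

    cands = []
    for rec in table:
        rp = rec.parsed
        if rp.genus not in within:
            continue
        gd = within[rp.genus] + (p.genus_hybrid != rp.genus_hybrid)
        if gd > cfg.max_distance_genus:
            continue
        ed = lev(p.epithet, rp.epithet) + (p.epithet_hybrid != rp.epithet_hybrid)
        if ed > cfg.max_distance_epithet:
            continue
        cands.append([rec, gd, ed, 0, None])
    if not cands:
        return None, 0, False
    if any(c[2] == 0 for c in cands):
        cands = [c for c in cands if c[2] == 0]

    if p.rank_marker:
        kept = []
        for c in cands:
            rp = c[0].parsed
            if not rp.rank_marker:
                continue
            if _rank_canon(rp.rank_marker) != _rank_canon(p.rank_marker):
                continue
            di = lev(p.infra_epithet, rp.infra_epithet)
            if di > cfg.max_distance_infra:
                continue
            c[3] = di
            kept.append(c)
        cands = kept
        if not cands:
            return None, 0, False
        if any(c[3] == 0 for c in cands):
            cands = [c for c in cands if c[3] == 0]
    else:
        cands = [c for c in cands if not c[0].parsed.rank_marker]
        if not cands:
            return None, 0, False

    for c in cands:
        if p.authority:
            ra = c[0].parsed.authority
            if cfg.fuzzy_authority:
                da = lev(p.authority, ra)
                c[4] = da if da <= cfg.max_distance_authority else None
            else:
                c[4] = 0 if p.authority == ra else None

    def key(c):
        rec, gd, ed, di, da = c
        total = gd + ed + di + (da if da is not None else 0)
        penalty = 1 if (p.authority and da is None) else 0
        return (total, penalty, STATUS_RANK[rec.status], rec.input_name)

    cands.sort(key=key)
    best = cands[0]
    ambiguous = len(cands) > 1 and key(cands[0])[:3] == key(cands[1])[:3]
    return best[0].input_name, key(best)[0], ambiguous


def oracle_flatten_target(name: str, table) -> str | None:
    """Follow accepted-name pointers naively until a non-synonym."""
    seen = set()
    current = table.lookup(name)
    while current is not None and current.status == "synonym":
        if current.input_name in seen:
            return None
        seen.add(current.input_name)
        current = table.lookup(current.accepted_name)
    if current is None or current.status != "accepted":
        return None
    return current.input_name
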