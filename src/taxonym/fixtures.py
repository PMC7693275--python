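"""Synthetic backbone and query generation with known ground truth.

Everything the other modules need for testing — backbones with
configurable fractions of synonyms, chains, hybrids, infraspecific
names, homonyms and injected defects, plus corrupted query names — is
produced here deterministically from a seed, together with truth
metadata describing exactly what was injected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from random import Random

from . import parser as _parser
from .distance import edit_distance
from .errors import FixtureSpecError
from .reference import (
    ACCEPTED,
    SYNONYM,
    UNRESOLVED,
    ReferenceRecord,
    ReferenceTable,
    SummaryStats,
    make_record,
)

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "CorruptionRecord",
    "generate_reference",
    "corrupt_query",
    "margin_pool",
]

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"
_GENUS_ENDINGS = ("us", "a", "um", "ia", "ella", "aria", "opsis")
_EPITHET_ENDINGS = ("us", "a", "um", "is", "ii", "ense", "oides", "ifolia", "icola")
_INFRA_RANKS = ("subsp.", "var.", "f.")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for the synthetic backbone generator.

    Fractions are relative to the number of accepted species generated
    in step one; ``chain_fraction`` is the share of synonyms whose
    cross-reference points at another synonym (pre-flattening) and
    ``chain_lengths`` additionally injects explicit chains of the given
    number of synonym hops.
    """

    n_genera: int = 10
    species_per_genus: tuple[int, int] = (3, 8)
    synonym_fraction: float = 0.0
    chain_fraction: float = 0.0
    chain_lengths: tuple[int, ...] = ()
    infraspecific_fraction: float = 0.0
    hybrid_fraction: float = 0.0
    unresolved_fraction: float = 0.0
    homonym_pairs: int = 0
    n_dangling: int = 0
    n_cycles: int = 0
    n_duplicates: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "synonym_fraction",
            "chain_fraction",
            "infraspecific_fraction",
            "hybrid_fraction",
            "unresolved_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genera", "homonym_pairs", "n_dangling", "n_cycles", "n_duplicates"):
            if getattr(self, name) < 0:
                raise FixtureSpecError(f"{name} must be >= 0")
        lo, hi = self.species_per_genus
        if lo < 1 or hi < lo:
            raise FixtureSpecError(
                f"species_per_genus must be a range with 1 <= lo <= hi, got {self.species_per_genus}"
            )
        if any(length < 2 for length in self.chain_lengths):
            raise FixtureSpecError("chain_lengths entries must be >= 2")


@dataclass
class FixtureTruth:
    """What :func:`generate_reference` injected, for oracle checks."""

    spec: FixtureSpec
    expected_summary: SummaryStats
    roles: dict[str, str] = field(default_factory=dict)
    chain_paths: list[list[str]] = field(default_factory=list)
    n_chained: int = 0
    dangling_names: list[str] = field(default_factory=list)
    cycle_pairs: list[tuple[str, str]] = field(default_factory=list)
    duplicate_names: list[str] = field(default_factory=list)
    homonym_names: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CorruptionRecord:
    """A query name derived from a true name by k random edits."""

    true_name: str
    corrupted_name: str
    component: str
    n_edits: int
    margin_ok: bool


def _syllable(rng: Random) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS)


def _word(rng: Random, n_syllables: int, endings: tuple[str, ...]) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables)) + rng.choice(endings)


def _unique_word(
    rng: Random, taken: set[str], endings: tuple[str, ...], *, capital: bool
) -> str:
    for attempt in range(1000):
        n = 2 + rng.randrange(3) + attempt // 100  # widen the space if crowded
        w = _word(rng, n, endings)
        if capital:
            w = w.capitalize()
        if w not in taken:
            taken.add(w)
            return w
    raise FixtureSpecError("name space exhausted while generating unique words")


def _authority(rng: Random) -> str:
    """A canonical authority string (stable under normalization)."""

    def author() -> str:
        initials = "".join(
            rng.choice("ABCDEFGHJKLMNPRSTW") + "." for _ in range(rng.randrange(3))
        )
        surname = _word(rng, 1 + rng.randrange(2), ("n", "r", "l", "m")).capitalize()
        return initials + surname + "."

    style = rng.random()
    if style < 0.6:
        return author()
    if style < 0.85:
        return f"{author()} & {author()}"
    return f"{author()} & al."


def generate_reference(spec: FixtureSpec) -> tuple[ReferenceTable, FixtureTruth]:
    """Generate a synthetic backbone plus its truth metadata.

    Deterministic per ``spec.seed``: the same spec yields an identical
    table (record-for-record) on every call.
    """
    rng = Random(spec.seed)
    genus_names: set[str] = set()
    records: list[ReferenceRecord] = []
    roles: dict[str, str] = {}

    def add(record: ReferenceRecord, role: str) -> ReferenceRecord:
        records.append(record)
        roles.setdefault(record.input_name, role)
        return record

    # step 1: accepted species
    species: list[ReferenceRecord] = []
    epithets_by_genus: dict[str, set[str]] = {}
    for gi in range(spec.n_genera):
        genus = _unique_word(rng, genus_names, _GENUS_ENDINGS, capital=True)
        epithets_by_genus[genus] = set()
        family = f"Familia{gi % max(1, spec.n_genera // 2)}ceae"
        order = f"Ordo{gi % max(1, spec.n_genera // 3)}ales"
        for _ in range(rng.randint(*spec.species_per_genus)):
            epithet = _unique_word(
                rng, epithets_by_genus[genus], _EPITHET_ENDINGS, capital=False
            )
            rec = make_record(
                f"{genus} {epithet} {_authority(rng)}",
                ACCEPTED,
                family=family,
                order=order,
            )
            rec.accepted_name = rec.input_name
            species.append(add(rec, "accepted_species"))

    n_species = len(species)

    # step 2: hybrids — flag a subset of the accepted species
    n_hybrids = round(spec.hybrid_fraction * n_species)
    hybrid_recs = rng.sample(species, n_hybrids)
    for rec in hybrid_recs:
        del roles[rec.input_name]
        rec.parsed.epithet_hybrid = True
        rec.input_name = rec.parsed.canonical()
        rec.accepted_name = rec.input_name
        roles[rec.input_name] = "hybrid"
    non_hybrid = [r for r in species if not r.parsed.is_hybrid]

    # step 3: infraspecific accepted names under non-hybrid species
    n_infra = round(spec.infraspecific_fraction * n_species)
    if n_infra > len(non_hybrid):
        raise FixtureSpecError("infraspecific_fraction infeasible for this spec")
    for parent in rng.sample(non_hybrid, n_infra):
        p = parent.parsed
        infra = _unique_word(
            rng, epithets_by_genus[p.genus], _EPITHET_ENDINGS, capital=False
        )
        rank = rng.choice(_INFRA_RANKS)
        rec = make_record(
            f"{p.genus} {p.epithet} {rank} {infra} {_authority(rng)}",
            ACCEPTED,
            family=parent.family,
            order=parent.order,
        )
        rec.accepted_name = rec.input_name
        add(rec, "accepted_infraspecific")

    # step 4: accepted homonyms (same binomial, different authority)
    if spec.homonym_pairs > len(non_hybrid):
        raise FixtureSpecError("homonym_pairs exceeds available species names")
    homonyms: list[tuple[str, str]] = []
    for parent in rng.sample(non_hybrid, spec.homonym_pairs):
        p = parent.parsed
        for _ in range(100):
            auth = _authority(rng)
            if auth != p.authority:
                break
        rec = make_record(
            f"{p.genus} {p.epithet} {auth}",
            ACCEPTED,
            family=parent.family,
            order=parent.order,
        )
        rec.accepted_name = rec.input_name
        add(rec, "accepted_homonym")
        homonyms.append((parent.input_name, rec.input_name))

    n_accepted_species_rank = n_species - n_hybrids + spec.homonym_pairs

    # step 5: unresolved names
    n_unresolved = round(spec.unresolved_fraction * n_species)
    for _ in range(n_unresolved):
        genus = rng.choice(sorted(epithets_by_genus))
        epithet = _unique_word(rng, epithets_by_genus[genus], _EPITHET_ENDINGS, capital=False)
        add(
            make_record(f"{genus} {epithet} {_authority(rng)}", UNRESOLVED),
            "unresolved",
        )

    # step 6: synonyms, a fraction of which chain onto other synonyms
    n_synonyms = round(spec.synonym_fraction * n_species)
    synonyms: list[ReferenceRecord] = []
    accepted_pool = [r for r in records if r.status == ACCEPTED]
    for _ in range(n_synonyms):
        genus = rng.choice(sorted(epithets_by_genus))
        epithet = _unique_word(rng, epithets_by_genus[genus], _EPITHET_ENDINGS, capital=False)
        target = rng.choice(accepted_pool)
        rec = make_record(
            f"{genus} {epithet} {_authority(rng)}", SYNONYM, target.input_name
        )
        synonyms.append(add(rec, "synonym"))

    n_chained = round(spec.chain_fraction * n_synonyms)
    if n_chained >= n_synonyms and n_chained > 0:
        raise FixtureSpecError("chain_fraction requires at least one unchained synonym")
    for i in range(n_chained):
        # point forward in the synonym list: guaranteed acyclic
        target = synonyms[rng.randrange(i + 1, n_synonyms)]
        synonyms[i].accepted_name = target.input_name
        roles[synonyms[i].input_name] = "chained_synonym"

    chain_paths: list[list[str]] = []
    total_chained = n_chained
    for length in spec.chain_lengths:
        terminal = rng.choice(accepted_pool)
        chain_recs: list[ReferenceRecord] = []
        for _ in range(length):
            genus = rng.choice(sorted(epithets_by_genus))
            epithet = _unique_word(
                rng, epithets_by_genus[genus], _EPITHET_ENDINGS, capital=False
            )
            chain_recs.append(
                make_record(f"{genus} {epithet} {_authority(rng)}", SYNONYM)
            )
        for link, nxt in zip(chain_recs, chain_recs[1:]):
            link.accepted_name = nxt.input_name
        chain_recs[-1].accepted_name = terminal.input_name
        for j, rec in enumerate(chain_recs):
            add(rec, "chained_synonym" if j < length - 1 else "synonym")
        total_chained += length - 1
        chain_paths.append([r.input_name for r in chain_recs] + [terminal.input_name])

    n_synonyms_total = n_synonyms + sum(spec.chain_lengths)

    # step 7: injected defects
    dangling_names: list[str] = []
    for i in range(spec.n_dangling):
        genus = rng.choice(sorted(epithets_by_genus))
        epithet = _unique_word(rng, epithets_by_genus[genus], _EPITHET_ENDINGS, capital=False)
        rec = make_record(
            f"{genus} {epithet} {_authority(rng)}",
            SYNONYM,
            f"Absentia fabricata{i} Xx.",
        )
        add(rec, "dangling_synonym")
        dangling_names.append(rec.input_name)

    cycle_pairs: list[tuple[str, str]] = []
    for _ in range(spec.n_cycles):
        pair = []
        for _ in range(2):
            genus = rng.choice(sorted(epithets_by_genus))
            epithet = _unique_word(
                rng, epithets_by_genus[genus], _EPITHET_ENDINGS, capital=False
            )
            pair.append(make_record(f"{genus} {epithet} {_authority(rng)}", SYNONYM))
        pair[0].accepted_name = pair[1].input_name
        pair[1].accepted_name = pair[0].input_name
        add(pair[0], "cycle_member")
        add(pair[1], "cycle_member")
        cycle_pairs.append((pair[0].input_name, pair[1].input_name))

    duplicate_names: list[str] = []
    if spec.n_duplicates > len(species):
        raise FixtureSpecError("n_duplicates exceeds available species records")
    for parent in rng.sample(species, spec.n_duplicates):
        add(dataclasses.replace(parent, extras=dict(parent.extras)), "duplicate")
        duplicate_names.append(parent.input_name)

    rng.shuffle(records)
    table = ReferenceTable(records, provenance=f"fixture(seed={spec.seed})")

    n_dup_species = sum(
        1 for n in duplicate_names if not table.lookup(n).parsed.is_hybrid
    )
    n_dup_hybrid = spec.n_duplicates - n_dup_species
    expected = SummaryStats(
        total_names=len(records),
        accepted_species=n_accepted_species_rank + n_dup_species,
        accepted_incl_infraspecific=n_accepted_species_rank + n_infra + n_dup_species,
        accepted_infraspecific=n_infra,
        natural_hybrids=n_hybrids + n_dup_hybrid,
        synonyms=n_synonyms_total + spec.n_dangling + 2 * spec.n_cycles,
        unresolved=n_unresolved,
        genera_accepted=len(epithets_by_genus),
        genera_all=len({r.parsed.genus for r in records}),
        families=len({r.family for r in records if r.status == ACCEPTED and r.family}),
        orders=len({r.order for r in records if r.status == ACCEPTED and r.order}),
        unresolved_by_genus={},
    )
    truth = FixtureTruth(
        spec=spec,
        expected_summary=expected,
        roles=roles,
        chain_paths=chain_paths,
        n_chained=total_chained,
        dangling_names=dangling_names,
        cycle_pairs=cycle_pairs,
        duplicate_names=duplicate_names,
        homonym_names=homonyms,
    )
    return table, truth


_COMPONENT_ATTR = {
    "genus": "genus",
    "epithet": "epithet",
    "infra": "infra_epithet",
    "authority": "authority",
}


def _apply_edits(word: str, k: int, rng: Random) -> str:
    chars = list(word)
    for _ in range(k):
        ops = ["substitute", "insert"]
        if len(chars) > 1:
            ops.append("delete")
        op = rng.choice(ops)
        if op == "substitute":
            i = rng.randrange(len(chars))
            chars[i] = rng.choice([c for c in "abcdefghijklmnopqrstuvwxyz" if c != chars[i]])
        elif op == "insert":
            i = rng.randrange(len(chars) + 1)
            chars.insert(i, rng.choice("abcdefghijklmnopqrstuvwxyz"))
        else:
            del chars[rng.randrange(len(chars))]
    return "".join(chars)


def margin_pool(table: ReferenceTable, p: _parser.ParsedName, component: str) -> list[str]:
    """Competing reference values for a component of query *p*.

    For the genus that is every reference genus; for the epithet, the
    (hybrid-suffixed) epithets within the query's genus; for the
    infraspecific epithet, the infra names under the query's binomial.
    """
    if component == "genus":
        return sorted(table.genus_index)
    if component == "epithet":
        recs = table.genus_index.get(p.genus, [])
        return sorted(
            {
                r.parsed.epithet + ("_x" if r.parsed.epithet_hybrid else "")
                for r in recs
            }
        )
    if component == "infra":
        recs = table.genus_index.get(p.genus, [])
        return sorted(
            {
                r.parsed.infra_epithet
                for r in recs
                if r.parsed.epithet == p.epithet and r.parsed.infra_epithet
            }
        )
    raise ValueError(f"unsupported component {component!r}")


def corrupt_query(
    name: str,
    component: str,
    k: int,
    seed: int,
    pool: list[str] | None = None,
) -> CorruptionRecord:
    """Apply exactly *k* random character edits to one component of *name*.

    ``margin_ok`` is computed against *pool* (competing reference values
    for the component, e.g. from :func:`margin_pool`): true when no
    value other than the original lies within *k* edits of the corrupted
    component.

    Raises
    ------
    FixtureSpecError
        If *k* exceeds the component length or the component is absent.
    """
    p = _parser.parse(name)
    attr = _COMPONENT_ATTR.get(component)
    if attr is None:
        raise FixtureSpecError(f"unknown component {component!r}")
    word = getattr(p, attr)
    if not word:
        raise FixtureSpecError(f"component {component!r} not present in {name!r}")
    if k > len(word):
        raise FixtureSpecError(
            f"cannot apply {k} edits to {component!r} of length {len(word)}"
        )
    rng = Random(seed)
    corrupted = word
    for _ in range(500):
        cand = _apply_edits(word, k, rng)
        if component == "genus":
            cand = cand[:1].upper() + cand[1:].lower()
        if edit_distance(cand, word) == k and (k == 0 or cand != word):
            corrupted = cand
            break
    else:  # pragma: no cover - virtually impossible for k <= len(word)
        raise FixtureSpecError(f"could not realize exactly {k} edits on {word!r}")

    p2 = dataclasses.replace(p, **{attr: corrupted}, warnings=[])
    rendered_true = word + ("_x" if component == "epithet" and p.epithet_hybrid else "")
    rendered_corrupt = corrupted + (
        "_x" if component == "epithet" and p.epithet_hybrid else ""
    )
    margin_ok = True
    if pool is not None:
        margin_ok = all(
            edit_distance(rendered_corrupt, other) > k
            for other in pool
            if other != rendered_true
        )
    return CorruptionRecord(
        true_name=p.canonical(),
        corrupted_name=p2.canonical(),
        component=component,
        n_edits=k,
        margin_ok=margin_ok,
    )
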