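"""Standardization and decomposition of botanical name strings.

A submitted name is a space-delimited sequence: genus, epithet, an
optional infraspecific rank marker plus infraspecific epithet, and an
optional authority.  Hybrids carry a literal ``_x`` suffix on the genus
(intergeneric) or the epithet (interspecific); the legacy annotations
``x`` / ``x_`` placed *before* a token are rewritten into that form.
The multiplication sign U+00D7 is rejected outright.

The module is pure-string: it never consults a reference table.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources

from .errors import HybridNotationError, NameParseError

__all__ = [
    "RANK_MARKERS",
    "ParsedName",
    "standardize_input",
    "parse_name",
    "parse",
    "format_name",
    "normalize_authority",
    "normalize_orthography",
]

#: Recognised infraspecific rank markers (matched case-insensitively,
#: only at token position 3 of a submitted name).
RANK_MARKERS = ("subsp.", "var.", "forma", "ssp.", "f.", "subvar.", "subf.")

_RANK_SET = frozenset(RANK_MARKERS)

#: U+00D7, the typographic hybrid sign; not accepted in input.
HYBRID_SIGN = "×"

_HYBRID_SUFFIX = "_x"

_INITIAL_RE = re.compile(r"^(?:[A-Z]\.)+$")
_AUTHOR_SUFFIXES = frozenset({"f.", "fil."})
_AUTHOR_SPLIT_RE = re.compile(r"\s*(?:,|&)\s*")
_EX_SPLIT_RE = re.compile(r"\s+ex\s+")


def _load_transliteration() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("taxonym.data").joinpath("transliteration.tsv").read_text("utf-8")
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        src, _, dst = line.partition("\t")
        table[src] = dst
    return table


_TRANSLIT = _load_transliteration()


@dataclass
class ParsedName:
    """Structured decomposition of a scientific name string.

    ``warnings`` collects normalization notes accrued while parsing and
    is excluded from equality comparisons.
    """

    genus: str
    epithet: str
    genus_hybrid: bool = False
    epithet_hybrid: bool = False
    rank_marker: str = ""  # "" means no infraspecific rank
    infra_epithet: str = ""
    authority: str = ""
    warnings: list[str] = field(default_factory=list, compare=False, repr=False)

    @property
    def is_hybrid(self) -> bool:
        return self.genus_hybrid or self.epithet_hybrid

    @property
    def is_infraspecific(self) -> bool:
        return bool(self.rank_marker)

    def name_key(self) -> tuple:
        """Identity of the name ignoring the authority."""
        return (
            self.genus,
            self.genus_hybrid,
            self.epithet,
            self.epithet_hybrid,
            self.rank_marker,
            self.infra_epithet,
        )

    def canonical(self) -> str:
        return format_name(self)


def standardize_input(raw: str) -> str:
    """Return *raw* rewritten into the canonical input format.

    Collapses whitespace and rewrites the hybrid annotations ``x`` and
    ``x_`` preceding the genus or the epithet into a trailing ``_x`` on
    that token.

    Raises
    ------
    HybridNotationError
        If the name contains the multiplication sign U+00D7.
    NameParseError
        If *raw* is empty or whitespace-only.
    """
    if raw is None or not raw.strip():
        raise NameParseError("empty name string")
    if HYBRID_SIGN in raw:
        raise HybridNotationError(
            "the multiplication sign (U+00D7) is not accepted as a hybrid "
            "marker; use a trailing '_x' on the genus or epithet instead"
        )
    toks = raw.split()
    out: list[str] = []
    i = 0
    while i < len(toks):
        tok = toks[i]
        # hybrid annotations are only meaningful ahead of the genus or
        # the epithet, i.e. while fewer than two name tokens were emitted
        if len(out) < 2:
            if tok.lower() == "x" and i + 1 < len(toks):
                nxt = toks[i + 1]
                if not nxt.endswith(_HYBRID_SUFFIX):
                    nxt += _HYBRID_SUFFIX
                out.append(nxt)
                i += 2
                continue
            if tok.lower().startswith("x_") and len(tok) > 2:
                base = tok[2:]
                if not base.endswith(_HYBRID_SUFFIX):
                    base += _HYBRID_SUFFIX
                out.append(base)
                i += 1
                continue
        out.append(tok)
        i += 1
    return " ".join(out)


def _strip_hybrid(token: str) -> tuple[str, bool]:
    if token.endswith(_HYBRID_SUFFIX):
        return token[: -len(_HYBRID_SUFFIX)], True
    return token, False


def normalize_orthography(word: str, warnings: list[str] | None = None) -> str:
    """Transliterate *word* to the A-Z/a-z/'-' alphabet.

    Characters are first looked up in the shipped transliteration table
    (umlauts expand to digraphs, accents are stripped); anything still
    outside the alphabet after Unicode decomposition is dropped and a
    warning is recorded.  Idempotent.
    """
    out: list[str] = []
    for ch in word:
        if "A" <= ch <= "Z" or "a" <= ch <= "z" or ch == "-":
            out.append(ch)
            continue
        if ch in _TRANSLIT:
            out.append(_TRANSLIT[ch])
            continue
        base = unicodedata.normalize("NFKD", ch)
        base = "".join(c for c in base if not unicodedata.combining(c))
        if len(base) == 1 and ("A" <= base <= "Z" or "a" <= base <= "z"):
            out.append(base)
        elif warnings is not None:
            warnings.append(f"dropped invalid character {ch!r} from {word!r}")
    return "".join(out)


def _compact_author(author: str) -> str:
    """Remove spaces inside one author name.

    Spaces after single-initial tokens ("C." "F." "W.") and before the
    filial suffixes "f."/"fil." are removed; everything else (multi-word
    surnames, hyphenated names) is left intact.
    """
    tokens = author.split()
    if not tokens:
        return ""
    merged = [tokens[0]]
    raw_prev = tokens[0]
    for tok in tokens[1:]:
        if _INITIAL_RE.match(raw_prev) or (
            tok in _AUTHOR_SUFFIXES and merged[-1].endswith(".")
        ):
            merged[-1] += tok
        else:
            merged.append(tok)
        raw_prev = tok
    return " ".join(merged)


def _normalize_author_list(part: str) -> str:
    authors = [a for a in (_compact_author(a) for a in _AUTHOR_SPLIT_RE.split(part)) if a]
    if not authors:
        return ""
    if len(authors) >= 3:
        return authors[0] + " & al."
    return " & ".join(authors)


def normalize_authority(auth: str) -> str:
    """Canonicalize an authority string.

    Spaces within abbreviated author names are removed, two authors are
    joined by `` & ``, three or more are truncated to the first author
    followed by ``& al.``.  `` ex `` separators are preserved.  Empty
    input yields the empty string; the function is idempotent.
    """
    auth = " ".join((auth or "").split())
    if not auth:
        return ""
    parts = _EX_SPLIT_RE.split(auth)
    return " ex ".join(filter(None, (_normalize_author_list(p) for p in parts)))


def parse_name(normalized: str) -> ParsedName:
    """Decompose a standardized name string into its components.

    Token 1 is the genus, token 2 the epithet.  When more than three
    tokens are present and the third is a rank marker, token 4 is the
    infraspecific epithet; otherwise everything after the epithet is
    authority.  Hybrid ``_x`` suffixes are stripped into flags.

    Raises
    ------
    NameParseError
        If fewer than two tokens are supplied.
    """
    toks = normalized.split()
    if len(toks) < 2:
        raise NameParseError(
            f"both a genus name and an epithet are required, got {normalized!r}"
        )
    warnings: list[str] = []

    genus_tok, genus_hybrid = _strip_hybrid(toks[0])
    epithet_tok, epithet_hybrid = _strip_hybrid(toks[1])
    genus = normalize_orthography(genus_tok, warnings)
    genus = genus[:1].upper() + genus[1:].lower()
    epithet = normalize_orthography(epithet_tok, warnings).lower()

    rank_marker = ""
    infra = ""
    rest = toks[2:]
    if len(toks) > 3 and toks[2].lower() in _RANK_SET:
        rank_marker = toks[2].lower()
        infra = normalize_orthography(toks[3], warnings).lower()
        rest = toks[4:]
    elif len(toks) == 3 and toks[2].lower() in _RANK_SET:
        warnings.append(
            f"rank marker {toks[2]!r} without an infraspecific epithet was dropped"
        )
        rest = []

    authority = normalize_authority(" ".join(rest))
    return ParsedName(
        genus=genus,
        epithet=epithet,
        genus_hybrid=genus_hybrid,
        epithet_hybrid=epithet_hybrid,
        rank_marker=rank_marker,
        infra_epithet=infra,
        authority=authority,
        warnings=warnings,
    )


def parse(raw: str) -> ParsedName:
    """Convenience: :func:`standardize_input` followed by :func:`parse_name`."""
    return parse_name(standardize_input(raw))


def format_name(p: ParsedName) -> str:
    """Render a :class:`ParsedName` back into its canonical string form."""
    toks = [
        p.genus + (_HYBRID_SUFFIX if p.genus_hybrid else ""),
        p.epithet + (_HYBRID_SUFFIX if p.epithet_hybrid else ""),
    ]
    if p.rank_marker:
        toks.append(p.rank_marker)
        toks.append(p.infra_epithet)
    if p.authority:
        toks.append(p.authority)
    return " ".join(toks)
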