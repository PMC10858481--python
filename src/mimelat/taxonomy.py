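"""QIIME-style taxonomy lineage strings.

Lineages are semicolon-separated, optionally carrying the conventional
single-letter rank prefixes (``k__Bacteria;p__Firmicutes;...``).  Ranks run
kingdom -> species in canonical order; trailing ranks may be absent and
internal ranks may be present but empty (``c__``), which is how amplicon
classifiers mark unresolved levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
_PREFIX_TO_RANK = {p: r for p, r in zip(RANK_PREFIXES, RANKS)}


@dataclass(frozen=True)
class TaxonomyLineage:
    """An ordered kingdom->species lineage.

    ``levels`` holds one ``(rank, name)`` pair per token of the source
    string, in canonical rank order; unresolved internal ranks keep an empty
    name.  ``depth`` counts the named (non-empty) ranks.
    """

    levels: tuple[tuple[str, str], ...]
    prefixed: bool = field(default=True, compare=False)

    @property
    def depth(self) -> int:
        return sum(1 for _, name in self.levels if name)

    def name_at(self, rank: str) -> str | None:
        """Name at ``rank``, or None if the rank is absent/unnamed."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        for r, name in self.levels:
            if r == rank:
                return name if name else None
        return None

    def label_at(self, rank: str) -> str | None:
        """Lineage string truncated at ``rank`` (None if unnamed there)."""
        if self.name_at(rank) is None:
            return None
        upto = RANKS.index(rank) + 1
        return render_taxonomy(
            TaxonomyLineage(self.levels[:upto], prefixed=self.prefixed)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_taxonomy(self)


def parse_taxonomy(label: str) -> TaxonomyLineage:
    """Parse a semicolon-separated lineage string.

    Tokens may carry QIIME prefixes (``k__``, ``p__``, ...); unprefixed
    tokens are assigned ranks positionally.  Raises on an empty string.
    """
    if not label or not label.strip():
        raise ValueError("empty lineage")
    tokens = [t.strip() for t in label.split(";")]
    if len(tokens) > len(RANKS):
        raise ValueError(f"lineage has {len(tokens)} levels, max {len(RANKS)}")
    prefixed = any("__" in t for t in tokens)
    levels: list[tuple[str, str]] = []
    for i, tok in enumerate(tokens):
        if "__" in tok:
            prefix, _, name = tok.partition("__")
            rank = _PREFIX_TO_RANK.get(prefix.lower())
            if rank is None:
                raise ValueError(f"unknown rank prefix {prefix!r} in {label!r}")
            if rank != RANKS[i]:
                raise ValueError(
                    f"rank {rank!r} out of canonical order at position {i} in {label!r}"
                )
        else:
            rank, name = RANKS[i], tok
        levels.append((rank, name))
    return TaxonomyLineage(tuple(levels), prefixed=prefixed)


def render_taxonomy(lineage: TaxonomyLineage) -> str:
    """Render back to a lineage string (identity on well-formed inputs)."""
    parts = []
    for rank, name in lineage.levels:
        if lineage.prefixed:
            parts.append(f"{RANK_PREFIXES[RANKS.index(rank)]}__{name}")
        else:
            parts.append(name)
    return ";".join(parts)
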