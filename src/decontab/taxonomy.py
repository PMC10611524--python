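"""Taxonomic lineage parsing and rank handling.

Lineage strings come in two dialects: QIIME/Greengenes-style prefixed strings
(``k__Bacteria;p__Bacteroidetes;...;g__Prevotella``) and bare genus names
(``Prevotella``).  Rank prefixes are stripped on parsing; a bare name is
interpreted as a genus label.  Matching against lineage names elsewhere in the
package is case-insensitive and exact at a stated rank -- never substring or
fuzzy -- so excluding ``Prevotella`` can never drop ``Prevotellaceae``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical rank order, kingdom -> species.  Genus is the working resolution
#: for most amplicon analyses; species is optional.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "d": "kingdom",  # SILVA-style domain prefix maps onto the top rank
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

#: Annotation tokens that mean "no classification at this rank".
_UNCLASSIFIED_TOKENS = {"", "unclassified", "unidentified", "unknown", "na", "n/a"}


def _clean_segment(segment: str) -> tuple[str | None, str | None]:
    """Return (rank or None, name or None) for one ``;``-separated segment."""
    segment = segment.strip()
    rank = None
    if len(segment) >= 3 and segment[1:3] == "__":
        rank = _PREFIX_TO_RANK.get(segment[0].lower())
        segment = segment[3:]
    name = segment.strip().strip('"')
    if name.lower() in _UNCLASSIFIED_TOKENS:
        name = None
    return rank, name


@dataclass(frozen=True)
class TaxonomyLineage:
    """An ordered taxonomic annotation for one taxon.

    ``names`` maps rank label -> name; ranks with no classification are absent
    (or map to ``None``).  ``raw`` preserves the original annotation string.
    """

    names: dict[str, str | None] = field(default_factory=dict)
    raw: str = ""

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyLineage":
        """Parse a lineage string in either dialect.

        A string without ``;`` separators and without a rank prefix is taken
        to be a bare genus name.
        """
        text = text.strip()
        segments = [s for s in text.split(";") if s.strip() != ""]
        names: dict[str, str | None] = {}
        if len(segments) == 1 and "__" not in segments[0]:
            _, name = _clean_segment(segments[0])
            names["genus"] = name
            return cls(names=names, raw=text)
        positional = iter(RANKS)
        for segment in segments:
            rank, name = _clean_segment(segment)
            if rank is None:
                # unprefixed multi-segment string: assign ranks positionally
                rank = next(positional, None)
                if rank is None:
                    continue
            names[rank] = name
        return cls(names=names, raw=text)

    def name_at(self, rank: str) -> str | None:
        """The name at ``rank``, or None if unclassified there."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.names.get(rank)

    @property
    def genus(self) -> str | None:
        return self.names.get("genus")

    def deepest_classified(self, upto: str | None = None) -> tuple[str, str] | None:
        """Deepest (rank, name) with a classification, optionally at/above ``upto``."""
        limit = RANKS.index(upto) if upto is not None else len(RANKS) - 1
        for rank in reversed(RANKS[: limit + 1]):
            name = self.names.get(rank)
            if name is not None:
                return rank, name
        return None

    def key_up_to(self, rank: str) -> tuple[str | None, ...]:
        """Hashable lineage prefix kingdom..rank, for aggregation grouping."""
        limit = RANKS.index(rank)
        return tuple(self.names.get(r) for r in RANKS[: limit + 1])

    def label_at(self, rank: str) -> str:
        """Display label at ``rank``: the name, or ``unclassified_<parent>``.

        The parent is the deepest classified rank above ``rank``; a lineage
        with no classification at all is labelled ``unclassified_root``.
        """
        name = self.name_at(rank)
        if name is not None:
            return name
        limit = RANKS.index(rank)
        parent = self.deepest_classified(upto=RANKS[limit - 1]) if limit > 0 else None
        return f"unclassified_{parent[1]}" if parent else "unclassified_root"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw or ";".join(
            f"{r[0]}__{self.names.get(r) or ''}" for r in RANKS if r in self.names
        )
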