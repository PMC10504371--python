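"""GTDB-style taxonomic lineages and the lowest-common-ancestor operation.

A lineage is an ordered path over the seven canonical ranks
(domain, phylum, class, order, family, genus, species), each name carrying
its GTDB rank prefix (``d__``, ``p__``, ...). Lineages may be truncated:
once a rank is unassigned every deeper rank is unassigned too, which makes
longest-common-prefix comparison well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
N_RANKS = len(RANKS)


@dataclass(frozen=True)
class TaxLineage:
    """An ordered rank path; empty strings mark unassigned ranks.

    Names are stored without their rank prefix. Any gap below the first
    unassigned rank is closed by truncation, so ``names`` is always a
    prefix-assigned tuple of length seven.
    """

    names: tuple[str, ...] = field(default=("",) * N_RANKS)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        if len(names) > N_RANKS:
            raise ValueError(f"lineage has more than {N_RANKS} ranks: {names}")
        names = names + ("",) * (N_RANKS - len(names))
        # truncate at the first unassigned rank
        truncated: list[str] = []
        for name in names:
            if name == "":
                break
            truncated.append(name)
        truncated += [""] * (N_RANKS - len(truncated))
        object.__setattr__(self, "names", tuple(truncated))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_string(cls, text: str) -> "TaxLineage":
        """Parse a semicolon-delimited, GTDB-prefixed lineage string.

        Tokens are matched to ranks by their prefix; a bare empty prefix
        (``g__``) or a missing token leaves that rank unassigned.
        """
        names = [""] * N_RANKS
        if text and text.lower() != "unclassified":
            for token in text.split(";"):
                token = token.strip()
                if not token:
                    continue
                for i, prefix in enumerate(PREFIXES):
                    if token.startswith(prefix):
                        names[i] = token[len(prefix):]
                        break
                else:
                    raise ValueError(f"unrecognised lineage token {token!r}")
        return cls(tuple(names))

    @classmethod
    def unclassified(cls) -> "TaxLineage":
        return cls(("",) * N_RANKS)

    # -- properties --------------------------------------------------------

    @property
    def depth(self) -> int:
        """Number of assigned ranks (0 for an unclassified lineage)."""
        return sum(1 for n in self.names if n != "")

    @property
    def deepest_rank(self) -> str:
        """Name of the deepest assigned rank, or ``"unclassified"``."""
        d = self.depth
        return RANKS[d - 1] if d else "unclassified"

    @property
    def is_unclassified(self) -> bool:
        return self.depth == 0

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    @property
    def genus(self) -> str:
        return self.names[RANKS.index("genus")]

    def truncate(self, rank: str) -> "TaxLineage":
        """Lineage cut at (and including) the given rank."""
        k = RANKS.index(rank) + 1
        return TaxLineage(self.names[:k])

    def agrees_through(self, other: "TaxLineage", rank: str) -> bool:
        """True if the two lineages do not conflict at any rank down to
        ``rank`` — an unassigned rank on either side never conflicts."""
        k = RANKS.index(rank) + 1
        for a, b in zip(self.names[:k], other.names[:k]):
            if a and b and a != b:
                return False
        return True

    def to_string(self) -> str:
        return ";".join(
            p + n for p, n in zip(PREFIXES, self.names) if n != ""
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string() or "unclassified"


def lca(lineages: Iterable[TaxLineage]) -> TaxLineage:
    """Lowest common ancestor: the longest common rank-prefix of the inputs.

    Raises ``ValueError`` on an empty input set. A fully unclassified input
    lineage forces the unclassified result, since it shares no assigned
    rank with anything.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("LCA of an empty lineage set is undefined")
    first = lineages[0].names
    common: list[str] = []
    for i in range(N_RANKS):
        name = first[i]
        if name == "" or any(lin.names[i] != name for lin in lineages[1:]):
            break
        common.append(name)
    return TaxLineage(tuple(common))


def parse_lineages(strings: Sequence[str]) -> list[TaxLineage]:
    return [TaxLineage.from_string(s) for s in strings]
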