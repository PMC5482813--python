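"""Ternary intron presence-absence patterns.

A set of orthologous transcripts is summarized, per aligned CDS position, by
a ternary vector over species: 1 marks the last nucleotide of a non-terminal
exon (an intron starts immediately downstream), 0 any other coding
nucleotide, 2 a gap or a missing ortholog.  Columns containing at least one
1 are intron presence-absence *patterns*; identical vectors are collapsed
into unique patterns that carry their multiplicity, the positional metadata
of every occurrence, and a functionality label derived from human
functional-element annotations.

Filtering (applied in this order when collapsing):

1. columns whose fraction of 2s (over all species) is >= 0.45 are dropped;
2. columns without any 1 are dropped;
3. columns whose human entry is not 1 are dropped (functionality is only
   assessed for human introns).

Labels: *functional* if every occurrence of the unique pattern carries at
least one functional-element tag, *non-functional* if none does, *partial*
otherwise.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EXON",
    "JUNCTION",
    "MISSING",
    "MISSING_FRACTION_MAX",
    "ArchitectureAlignment",
    "TernaryColumn",
    "Occurrence",
    "UniquePattern",
    "encode_ternary",
    "collapse_and_label",
    "read_junction_table",
    "read_element_bed",
    "write_pattern_tsv",
    "read_pattern_tsv",
]

EXON, JUNCTION, MISSING = 0, 1, 2
#: columns with a missing-data fraction at or above this are filtered out
MISSING_FRACTION_MAX = 0.45

LABEL_FUNCTIONAL = "functional"
LABEL_NON_FUNCTIONAL = "non-functional"
LABEL_PARTIAL = "partial"


@dataclass
class ArchitectureAlignment:
    """Aligned gene architectures for one ortholog set.

    ``codes`` is an (n_species, n_columns) int matrix over {0: exon-internal,
    1: exon-end, 2: gap/missing}; rows follow ``species``.  ``elements`` maps
    a human junction column index to the element-type tags of the intron
    starting there.
    """

    set_id: str
    species: list[str]
    codes: np.ndarray
    elements: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.species):
            raise ValueError(
                f"set {self.set_id!r}: codes shape {self.codes.shape} does not "
                f"match {len(self.species)} species rows"
            )
        if not np.isin(self.codes, (EXON, JUNCTION, MISSING)).all():
            raise ValueError(f"set {self.set_id!r}: codes outside {{0,1,2}}")


@dataclass(frozen=True)
class Occurrence:
    """One pattern occurrence: where a ternary column came from."""

    set_id: str
    column: int
    position: int | None  # 1-based human CDS offset of the junction nucleotide
    cds_length: int | None  # human unaligned CDS length (nt)
    tags: tuple[str, ...] = ()


@dataclass
class TernaryColumn:
    values: np.ndarray  # per-species {0,1,2}
    occurrence: Occurrence

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.values)


@dataclass
class UniquePattern:
    """A distinct ternary vector with multiplicity, occurrences and label."""

    values: np.ndarray
    species: list[str]
    occurrences: list[Occurrence]
    label: str
    sublabels: dict[str, str] = field(default_factory=dict)

    @property
    def multiplicity(self) -> int:
        return len(self.occurrences)

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.values)

    def value_of(self, species: str) -> int:
        return int(self.values[self.species.index(species)])

    def pattern_string(self) -> str:
        return "".join(str(int(v)) for v in self.values)


def encode_ternary(arch: ArchitectureAlignment, human_species: str = "Homo_sapiens") -> list[TernaryColumn]:
    """Extract one :class:`TernaryColumn` per alignment column containing a 1.

    The human POSITION of a column is the count of human non-gap nucleotides
    from the CDS start through the junction-marking nucleotide inclusive
    (1-based); it is recorded only when the human entry of the column is 1.
    """
    codes = arch.codes
    has_junction = (codes == JUNCTION).any(axis=0)
    columns: list[TernaryColumn] = []
    if human_species in arch.species:
        h = arch.species.index(human_species)
        human_row = codes[h]
        human_nongap = np.cumsum(human_row != MISSING)
        human_len = int(human_nongap[-1]) if human_row.size else 0
    else:
        h = None
    for col in np.nonzero(has_junction)[0]:
        position = cds_length = None
        tags: tuple[str, ...] = ()
        if h is not None and codes[h, col] == JUNCTION:
            position = int(human_nongap[col])
            cds_length = human_len
            tags = tuple(arch.elements.get(int(col), ()))
        columns.append(
            TernaryColumn(
                values=codes[:, col].copy(),
                occurrence=Occurrence(arch.set_id, int(col), position, cds_length, tags),
            )
        )
    return columns


def _label_from_tag_flags(flags: list[bool]) -> str:
    if all(flags):
        return LABEL_FUNCTIONAL
    if not any(flags):
        return LABEL_NON_FUNCTIONAL
    return LABEL_PARTIAL


def collapse_and_label(
    columns: list[TernaryColumn],
    species: list[str],
    human_species: str = "Homo_sapiens",
    *,
    missing_fraction_max: float = MISSING_FRACTION_MAX,
) -> list[UniquePattern]:
    """Filter ternary columns and collapse them into labeled unique patterns.

    Sublabels are computed per element type with the same all/none/partial
    rule applied to occurrences bearing that specific tag.
    """
    if human_species not in species:
        raise ValueError(f"human species {human_species!r} not in species list")
    h = species.index(human_species)
    n = len(species)

    groups: "collections.OrderedDict[tuple[int, ...], list[TernaryColumn]]" = collections.OrderedDict()
    for col in columns:
        if col.values.shape != (n,):
            raise ValueError("ternary column length does not match species list")
        if (col.values == MISSING).sum() / n >= missing_fraction_max:
            continue
        if not (col.values == JUNCTION).any():
            continue
        if col.values[h] != JUNCTION:
            continue
        groups.setdefault(col.key, []).append(col)

    patterns: list[UniquePattern] = []
    for key, cols in groups.items():
        occurrences = [c.occurrence for c in cols]
        tagged = [len(o.tags) > 0 for o in occurrences]
        all_tags = sorted({t for o in occurrences for t in o.tags})
        sublabels = {
            tag: _label_from_tag_flags([tag in o.tags for o in occurrences])
            for tag in all_tags
        }
        patterns.append(
            UniquePattern(
                values=np.asarray(key, dtype=np.int8),
                species=list(species),
                occurrences=occurrences,
                label=_label_from_tag_flags(tagged),
                sublabels=sublabels,
            )
        )
    return patterns


# -- on-disk formats -------------------------------------------------------

def read_junction_table(path, species: list[str], human_species: str = "Homo_sapiens",
                        elements: dict[tuple[str, int], tuple[str, ...]] | None = None
                        ) -> list[ArchitectureAlignment]:
    """Read a per-species junction TSV into architecture alignments.

    Expected columns (tab-separated, ``#`` comments allowed)::

        set_id  species  cds_length  junctions

    ``junctions`` is a comma-separated list of 1-based aligned CDS offsets of
    exon-end nucleotides (empty for an intron-less transcript).  Coordinates
    are on a common, already-aligned CDS axis; a species without a row in a
    set is treated as missing (all 2s) and positions past a species'
    ``cds_length`` are gaps.  ``elements`` maps (set_id, human junction
    offset) to element-type tags, e.g. from :func:`read_element_bed`.
    """
    frame = pd.read_csv(
        path, sep="\t", comment="#",
        names=["set_id", "species", "cds_length", "junctions"],
        dtype={"set_id": str, "species": str, "junctions": str},
    )
    elements = elements or {}
    alignments = []
    for set_id, rows in frame.groupby("set_id", sort=True):
        unknown = set(rows["species"]) - set(species)
        if unknown:
            raise ValueError(f"set {set_id!r}: unknown species {sorted(unknown)}")
        width = int(rows["cds_length"].max())
        codes = np.full((len(species), width), MISSING, dtype=np.int8)
        for _, row in rows.iterrows():
            s = species.index(row["species"])
            length = int(row["cds_length"])
            codes[s, :length] = EXON
            juncs = str(row["junctions"]) if pd.notna(row["junctions"]) else ""
            for tok in juncs.split(","):
                tok = tok.strip()
                if not tok:
                    continue
                offset = int(tok)
                if not 1 <= offset <= length:
                    raise ValueError(
                        f"set {set_id!r} {row['species']}: junction offset {offset} "
                        f"outside CDS of length {length}"
                    )
                codes[s, offset - 1] = JUNCTION
        tags = {
            pos - 1: elems
            for (sid, pos), elems in elements.items()
            if sid == set_id
        }
        alignments.append(ArchitectureAlignment(str(set_id), list(species), codes, tags))
    return alignments


def read_element_bed(path) -> dict[tuple[str, int], tuple[str, ...]]:
    """Read functional-element annotations keyed by hosting junction.

    BED-like TSV with 0-based half-open intervals: ``set_id  start  end
    element_type``, where the interval covers the junction nucleotide of the
    hosting intron (so ``end = start + 1`` and the 1-based junction offset is
    ``end``).  Returns {(set_id, 1-based junction offset): tags}.
    """
    out: dict[tuple[str, int], list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            set_id, start, end = fields[0], int(fields[1]), int(fields[2])
            if end != start + 1:
                raise ValueError(
                    f"element interval [{start},{end}) must cover exactly the "
                    "junction nucleotide"
                )
            tag = fields[3] if len(fields) > 3 else "element"
            out.setdefault((set_id, end), []).append(tag)
    return {k: tuple(sorted(set(v))) for k, v in out.items()}


def write_pattern_tsv(patterns: list[UniquePattern], path) -> None:
    """Write unique patterns as TSV (pattern, multiplicity, label, occurrences)."""
    with open(path, "w") as fh:
        species = patterns[0].species if patterns else []
        fh.write("# species=" + ",".join(species) + "\n")
        fh.write("pattern\tmultiplicity\tlabel\toccurrences\n")
        for p in patterns:
            occ = ";".join(
                "{},{},{},{},{}".format(
                    o.set_id, o.column,
                    "" if o.position is None else o.position,
                    "" if o.cds_length is None else o.cds_length,
                    "|".join(o.tags),
                )
                for o in p.occurrences
            )
            fh.write(f"{p.pattern_string()}\t{p.multiplicity}\t{p.label}\t{occ}\n")


def read_pattern_tsv(path) -> list[UniquePattern]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# species="):
            raise ValueError("pattern TSV must start with a '# species=' line")
        species = header.split("=", 1)[1].split(",")
        fh.readline()  # column header
        patterns = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pattern_str, mult, label, occ_str = line.split("\t")
            occurrences = []
            for rec in occ_str.split(";"):
                if not rec:
                    continue
                set_id, column, position, cds_length, tags = rec.split(",")
                occurrences.append(Occurrence(
                    set_id=set_id,
                    column=int(column),
                    position=int(position) if position else None,
                    cds_length=int(cds_length) if cds_length else None,
                    tags=tuple(t for t in tags.split("|") if t),
                ))
            if len(occurrences) != int(mult):
                raise ValueError(f"multiplicity mismatch for pattern {pattern_str}")
            tagged = [len(o.tags) > 0 for o in occurrences]
            all_tags = sorted({t for o in occurrences for t in o.tags})
            patterns.append(UniquePattern(
                values=np.array([int(c) for c in pattern_str], dtype=np.int8),
                species=list(species),
                occurrences=occurrences,
                label=label,
                sublabels={
                    tag: _label_from_tag_flags([tag in o.tags for o in occurrences])
                    for tag in all_tags
                },
            ))
    return patterns
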