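"""Protein-level mutation catalog: parsing, isoform harmonization, domain
annotation, recurrence calling, and oncoprint/lolliplot table generation.

The unit of analysis is the protein change (e.g. ``T475M``): one amino-acid
substitution at a 1-based residue position in a named isoform numbering
frame.  Nuclear-receptor genes such as *PPARG* have isoforms that differ by
an N-terminal extension (PPARgamma2 is 28 residues longer than PPARgamma1),
so observations from different cohorts must be renumbered into a single
frame before identical changes can be counted as recurrent.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ProteinChange",
    "UnmappableChange",
    "Variant",
    "Stage",
    "Source",
    "IsoformMap",
    "DomainMap",
    "RecurrenceRecord",
    "ParseError",
    "ValidationError",
    "ContractError",
    "parse_protein_change",
    "harmonize_isoform",
    "annotate_domain",
    "call_recurrent",
    "build_lolliplot_table",
    "build_oncoprint_matrix",
    "read_mutation_table",
    "write_recurrence_table",
    "pparg2_domain_map",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ParseError(ValueError):
    """A mutation label does not match the expected grammar."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


class ContractError(ValueError):
    """A precondition between pipeline stages was violated."""


class Stage(str, Enum):
    NMIBC = "NMIBC"
    MIBC = "MIBC"
    CELL_LINE = "cell_line"
    UNKNOWN = "unknown"


class Source(str, Enum):
    COHORT = "cohort"
    EXTERNAL_DB = "external_db"


@dataclass(frozen=True, order=True)
class ProteinChange:
    """A single amino-acid substitution in protein coordinates.

    Positions are 1-based residue indices in the numbering frame named by
    ``isoform`` (e.g. ``"PPARG2"``).
    """

    ref_aa: str
    position: int
    alt_aa: str
    isoform: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS:
            raise ValidationError(f"invalid reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in AMINO_ACIDS:
            raise ValidationError(f"invalid alternate amino acid {self.alt_aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"reference and alternate amino acid are identical in "
                f"{self.ref_aa}{self.position}{self.alt_aa}"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    def render(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class UnmappableChange:
    """Marker for a change that has no equivalent in a target isoform frame.

    Produced when renumbering would land below the first residue of the
    target isoform, i.e. the change sits in sequence specific to the source
    isoform (PPARgamma2's N-terminal extension, for E3K and D7N).
    """

    change: ProteinChange
    target_isoform: str
    reason: str = "isoform-specific"


@dataclass(frozen=True)
class Variant:
    """One protein-level mutation observation in one sample."""

    sample_id: str
    cohort: str
    stage: Stage
    gene: str
    change: ProteinChange
    source: Source

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")


@dataclass(frozen=True)
class IsoformMap:
    """Affine renumbering between two isoform frames of the same protein.

    ``offset`` is added to positions in ``from_isoform`` coordinates to get
    ``to_isoform`` coordinates.  Target positions below ``min_valid_target``
    do not exist in the target isoform and are reported unmappable rather
    than clamped.
    """

    from_isoform: str
    to_isoform: str
    offset: int
    min_valid_target: int = 1

    def inverse(self) -> "IsoformMap":
        return IsoformMap(self.to_isoform, self.from_isoform, -self.offset,
                          self.min_valid_target)


# The +28 N-terminal extension distinguishing PPARgamma2 from PPARgamma1.
PPARG1_TO_PPARG2 = IsoformMap("PPARG1", "PPARG2", offset=28)


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping domain spans for one gene/isoform frame."""

    gene: str
    isoform: str
    domains: tuple  # of (name, start, end), 1-based inclusive
    landmarks: tuple = ()  # of (name, position)
    protein_length: int | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.domains:
            if start > end:
                raise ValidationError(f"domain {name}: start {start} > end {end}")
            if start <= prev_end:
                raise ValidationError(f"domain {name} overlaps the previous domain")
            prev_end = end
        length = self.length
        for name, pos in self.landmarks:
            if not (1 <= pos <= length):
                raise ValidationError(f"landmark {name} at {pos} outside protein")

    @property
    def length(self) -> int:
        if self.protein_length is not None:
            return self.protein_length
        return max(end for _, _, end in self.domains)


def pparg2_domain_map() -> DomainMap:
    """Default PPARgamma2-frame domain architecture.

    The ligand-binding domain span (231-505) matches the bacterially
    expressed LBD construct; the A/B (N-terminal) and DNA-binding domain
    boundaries follow standard nuclear-receptor annotation renumbered into
    the gamma2 frame and are overridable via configuration.
    """
    return DomainMap(
        gene="PPARG",
        isoform="PPARG2",
        domains=(("A/B", 1, 136), ("DBD", 137, 206), ("LBD", 231, 505)),
        landmarks=(("S112", 112), ("S273", 273)),
        protein_length=505,
    )


_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])(?:/([A-Z]))?$")


def parse_protein_change(label: str, isoform: str):
    """Parse a mutation label like ``"T475M"`` or ``"S427F/Y"``.

    Returns a single :class:`ProteinChange` for simple labels; the
    multi-allele form ``<ref><pos><alt1>/<alt2>`` expands to a list of two
    changes sharing the position.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ParseError(f"malformed protein change label {label!r}")
    ref, pos, alt1, alt2 = m.group(1), int(m.group(2)), m.group(3), m.group(4)
    first = ProteinChange(ref, pos, alt1, isoform)
    if alt2 is None:
        return first
    return [first, ProteinChange(ref, pos, alt2, isoform)]


def harmonize_isoform(change: ProteinChange, iso_map: IsoformMap):
    """Renumber ``change`` into ``iso_map.to_isoform`` coordinates.

    Returns the shifted :class:`ProteinChange`, or an
    :class:`UnmappableChange` when the shifted position falls below the
    lowest valid target position (the change is specific to the source
    isoform's extra sequence).
    """
    if change.isoform != iso_map.from_isoform:
        raise ContractError(
            f"change is in frame {change.isoform!r}, map expects "
            f"{iso_map.from_isoform!r}"
        )
    new_pos = change.position + iso_map.offset
    if new_pos < iso_map.min_valid_target:
        return UnmappableChange(change, iso_map.to_isoform)
    return ProteinChange(change.ref_aa, new_pos, change.alt_aa, iso_map.to_isoform)


def annotate_domain(change: ProteinChange, dm: DomainMap) -> str:
    """Name the domain containing the mutated residue, or ``"linker"``."""
    if change.isoform != dm.isoform:
        raise ContractError(
            f"change frame {change.isoform!r} does not match domain map frame "
            f"{dm.isoform!r}"
        )
    if change.position > dm.length:
        raise ValidationError(
            f"position {change.position} beyond protein length {dm.length}"
        )
    for name, start, end in dm.domains:
        if start <= change.position <= end:
            return name
    return "linker"


class RecurrenceBasis(str, Enum):
    COHORT_ONLY = "cohort_only"
    POOLED = "pooled"
    NONE = "none"


@dataclass(frozen=True)
class RecurrenceRecord:
    gene: str
    change: ProteinChange
    n_cohort: int
    n_external: int
    stages_seen: frozenset
    is_recurrent: bool
    recurrence_basis: RecurrenceBasis

    @property
    def n_total(self) -> int:
        return self.n_cohort + self.n_external


def _dedup_cohort(variants: Iterable[Variant]):
    """Collapse repeated reports of the same (sample, gene, change).

    External-database observations lack stable sample identity and are
    counted per reported occurrence.
    """
    seen: set = set()
    cohort: list[Variant] = []
    external: list[Variant] = []
    for v in variants:
        if v.source is Source.EXTERNAL_DB:
            external.append(v)
            continue
        key = (v.sample_id, v.gene, v.change)
        if key in seen:
            continue
        seen.add(key)
        cohort.append(v)
    return cohort, external


def call_recurrent(
    variants: Sequence[Variant],
    min_count: int = 2,
    pool_external: bool = False,
) -> list[RecurrenceRecord]:
    """Aggregate variants per distinct (gene, change) and flag recurrence.

    A change is recurrent when observed at least ``min_count`` times: in
    cohort samples alone when ``pool_external`` is false, or pooling cohort
    and external-database occurrences when true.  ``recurrence_basis``
    records whether the cohort evidence alone sufficed.
    """
    frames: dict[str, set] = defaultdict(set)
    for v in variants:
        frames[v.gene].add(v.change.isoform)
    for gene, isoforms in frames.items():
        if len(isoforms) > 1:
            raise ContractError(
                f"gene {gene} carries mixed isoform frames {sorted(isoforms)}; "
                "harmonize with harmonize_isoform first"
            )

    cohort, external = _dedup_cohort(variants)
    groups: dict = defaultdict(lambda: {"cohort": 0, "external": 0, "stages": set()})
    for v in cohort:
        g = groups[(v.gene, v.change)]
        g["cohort"] += 1
        g["stages"].add(v.stage)
    for v in external:
        g = groups[(v.gene, v.change)]
        g["external"] += 1
        g["stages"].add(v.stage)

    records = []
    for (gene, change), g in groups.items():
        n_cohort, n_external = g["cohort"], g["external"]
        n_total = n_cohort + n_external
        if n_cohort >= min_count:
            recurrent, basis = True, RecurrenceBasis.COHORT_ONLY
        elif pool_external and n_total >= min_count:
            recurrent, basis = True, RecurrenceBasis.POOLED
        else:
            recurrent, basis = False, RecurrenceBasis.NONE
        records.append(
            RecurrenceRecord(
                gene=gene,
                change=change,
                n_cohort=n_cohort,
                n_external=n_external,
                stages_seen=frozenset(g["stages"]),
                is_recurrent=recurrent,
                recurrence_basis=basis,
            )
        )
    records.sort(key=lambda r: (r.gene, r.change.position, -r.n_total,
                                r.change.alt_aa))
    return records


def build_lolliplot_table(
    records: Sequence[RecurrenceRecord], dm: DomainMap
) -> pd.DataFrame:
    """Per-change count table along the protein, ready for a lolliplot.

    One row per distinct change with positions ascending; duplicate change
    labels are aggregated so total counts are conserved.
    """
    rows: dict = {}
    for r in records:
        key = (r.change.position, r.change.render())
        if key in rows:
            rows[key]["n_cohort"] += r.n_cohort
            rows[key]["n_external"] += r.n_external
        else:
            rows[key] = {
                "position": r.change.position,
                "change": r.change.render(),
                "n_cohort": r.n_cohort,
                "n_external": r.n_external,
                "domain": annotate_domain(r.change, dm),
            }
    out = pd.DataFrame(
        sorted(rows.values(), key=lambda d: (d["position"], d["change"])),
        columns=["position", "change", "n_cohort", "n_external", "domain"],
    )
    return out


ALTERATION_CLASSES = ("none", "mutation", "amplification", "mutation+amplification")


def build_oncoprint_matrix(
    variants: Sequence[Variant],
    amplifications: Sequence[tuple],
    sample_order: Sequence[str],
) -> pd.DataFrame:
    """Sample-by-gene alteration-class matrix, columns ordered as given.

    ``sample_order`` is typically the activation-score ordering; every
    sample carrying a variant must appear in it.
    """
    order = list(sample_order)
    known = set(order)
    mutated: set = set()
    genes: set = set()
    for v in variants:
        if v.sample_id not in known:
            raise ContractError(
                f"sample {v.sample_id!r} has variants but is missing from "
                "sample_order"
            )
        mutated.add((v.sample_id, v.gene))
        genes.add(v.gene)
    amplified: set = set()
    for sample_id, gene in amplifications:
        if sample_id not in known:
            raise ContractError(
                f"sample {sample_id!r} has an amplification but is missing "
                "from sample_order"
            )
        amplified.add((sample_id, gene))
        genes.add(gene)
    gene_rows = sorted(genes)
    data = {}
    for s in order:
        col = []
        for g in gene_rows:
            has_mut = (s, g) in mutated
            has_amp = (s, g) in amplified
            if has_mut and has_amp:
                col.append("mutation+amplification")
            elif has_mut:
                col.append("mutation")
            elif has_amp:
                col.append("amplification")
            else:
                col.append("none")
        data[s] = col
    return pd.DataFrame(data, index=gene_rows, columns=order)


MUTATION_TABLE_COLUMNS = [
    "sample_id", "cohort", "stage", "gene", "protein_change", "isoform", "source",
]


def read_mutation_table(path) -> list[Variant]:
    """Read a mutation TSV (columns: sample_id, cohort, stage, gene,
    protein_change, isoform, source).  ``#`` comment lines are ignored and
    multi-allele labels expand to one variant per allele."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MUTATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"mutation table missing columns {missing}")
    variants: list[Variant] = []
    for row in df.itertuples(index=False):
        parsed = parse_protein_change(row.protein_change, row.isoform)
        changes = parsed if isinstance(parsed, list) else [parsed]
        for change in changes:
            variants.append(
                Variant(
                    sample_id=row.sample_id,
                    cohort=row.cohort,
                    stage=Stage(row.stage),
                    gene=row.gene,
                    change=change,
                    source=Source(row.source),
                )
            )
    return variants


def variants_to_frame(variants: Sequence[Variant]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": v.sample_id,
            "cohort": v.cohort,
            "stage": v.stage.value,
            "gene": v.gene,
            "protein_change": v.change.render(),
            "isoform": v.change.isoform,
            "source": v.source.value,
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS)


def write_recurrence_table(records: Sequence[RecurrenceRecord], path) -> None:
    """Write recurrence records as TSV with a fixed column order."""
    rows = [
        {
            "gene": r.gene,
            "position": r.change.position,
            "change": r.change.render(),
            "isoform": r.change.isoform,
            "n_cohort": r.n_cohort,
            "n_external": r.n_external,
            "n_total": r.n_total,
            "stages_seen": ",".join(sorted(s.value for s in r.stages_seen)),
            "is_recurrent": str(r.is_recurrent).lower(),
            "recurrence_basis": r.recurrence_basis.value,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene", "position", "change", "isoform", "n_cohort", "n_external",
            "n_total", "stages_seen", "is_recurrent", "recurrence_basis",
        ],
    ).to_csv(path, sep="\t", index=False)
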