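"""Seeded generators for cohorts, expression matrices, and toy structures.

These emulate the statistical structure of the bladder-tumor analyses —
rare recurrent mutations concentrated in an activation-high subgroup,
log-scale expression with signature genes shifted upward in that subgroup,
and a two-chain structure with a constructed dimer interface — so every
pipeline stage is testable without any external download.  Every generator
is deterministic given its spec and seed, and returns a truth record
holding the latent assignments needed to score recovery downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .structure import StructureModel, Residue, Atom
from .variants import (
    ProteinChange,
    Source,
    Stage,
    Variant,
    ValidationError,
)

__all__ = [
    "CohortSimSpec",
    "ExpressionSimSpec",
    "simulate_cohort",
    "simulate_expression",
    "make_toy_heterodimer",
    "write_pdb",
    "coupled_rates",
    "bladder_narrative_variants",
]


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of a simulated tumor cohort.

    Defaults mirror the magnitudes of the bladder cohorts analyzed: a few
    hundred tumors, a mutation rate of a few percent, and alteration odds
    concentrated in the activation-high (luminal-like) subgroup.
    """

    n_samples: int = 359
    stage_fractions: tuple = (("NMIBC", 199 / 359), ("MIBC", 160 / 359))
    mutation_rate: float = 14 / 359
    recurrent_positions: tuple = ()  # of (gene, ProteinChange, target_count)
    amplification_rate: float = 0.12
    subgroup_fraction: float = 0.5
    alteration_subgroup_odds_ratio: float = 8.0
    gene: str = "PPARG"
    isoform: str = "PPARG2"

    def __post_init__(self) -> None:
        for name, value in (
            ("mutation_rate", self.mutation_rate),
            ("amplification_rate", self.amplification_rate),
        ):
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.subgroup_fraction < 1.0):
            raise ValidationError("subgroup_fraction must lie in (0, 1)")
        if self.alteration_subgroup_odds_ratio <= 0:
            raise ValidationError("odds ratio must be positive")
        if sum(c for _, _, c in self.recurrent_positions) > self.n_samples:
            raise ValidationError(
                "recurrent target counts exceed the number of samples"
            )


def coupled_rates(overall: float, odds_ratio: float, subgroup_fraction: float):
    """Solve the two Bernoulli alteration rates (inside/outside a subgroup)
    from the overall rate, the target odds ratio, and the subgroup size.

    With subgroup fraction f and rates (p1, p0) the constraints are
    f*p1 + (1-f)*p0 = overall and [p1/(1-p1)] / [p0/(1-p0)] = odds_ratio;
    eliminating p1 leaves a monotone one-dimensional root problem in p0.
    """
    f = subgroup_fraction
    if odds_ratio == 1.0:
        return overall, overall
    if overall == 0.0:
        return 0.0, 0.0

    def p1_of(p0: float) -> float:
        odds0 = p0 / (1.0 - p0)
        odds1 = odds_ratio * odds0
        return odds1 / (1.0 + odds1)

    def g(p0: float) -> float:
        return f * p1_of(p0) + (1.0 - f) * p0 - overall

    eps = 1e-12
    p0 = brentq(g, eps, 1.0 - eps, xtol=1e-14)
    return p1_of(p0), p0


def simulate_cohort(spec: CohortSimSpec, seed: int):
    """Draw a cohort: mutation table, amplification table, subgroup labels,
    and the latent truth.

    Subgroup membership and per-sample alteration status are drawn so the
    alteration-vs-subgroup 2x2 has the spec's expected odds ratio.
    Recurrent changes then receive exactly their target counts among
    altered samples; remaining altered samples get unique background
    changes.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    stage_names = [s for s, _ in spec.stage_fractions]
    stage_probs = np.array([p for _, p in spec.stage_fractions], dtype=float)
    stage_probs = stage_probs / stage_probs.sum()
    stages = rng.choice(stage_names, size=n, p=stage_probs)

    in_subgroup = rng.random(n) < spec.subgroup_fraction
    p1, p0 = coupled_rates(
        spec.mutation_rate,
        spec.alteration_subgroup_odds_ratio,
        spec.subgroup_fraction,
    )
    mut_prob = np.where(in_subgroup, p1, p0)
    mutated = rng.random(n) < mut_prob
    mutated_ids = [s for s, m in zip(sample_ids, mutated) if m]

    targets = list(spec.recurrent_positions)
    needed = sum(c for _, _, c in targets)
    if needed > len(mutated_ids):
        raise ValidationError(
            f"spec asks for {needed} recurrent carriers but only "
            f"{len(mutated_ids)} samples were mutated at this seed"
        )
    assignment = rng.permutation(mutated_ids).tolist()
    rows = []
    stage_of = dict(zip(sample_ids, stages))
    for gene, change, count in targets:
        for _ in range(count):
            s = assignment.pop()
            rows.append((s, change, gene))
    background_positions = iter(range(600, 600 + len(assignment) + 1))
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for s in assignment:
        pos = next(background_positions)
        ref, alt = rng.choice(list(aa), size=2, replace=False)
        rows.append((s, ProteinChange(str(ref), pos, str(alt), spec.isoform),
                     spec.gene))

    variants = [
        Variant(
            sample_id=s,
            cohort="SIM",
            stage=Stage(stage_of[s]),
            gene=gene,
            change=change,
            source=Source.COHORT,
        )
        for s, change, gene in rows
    ]
    variants.sort(key=lambda v: (v.sample_id, v.gene, v.change))

    amplified = rng.random(n) < spec.amplification_rate
    amp_table = pd.DataFrame(
        {
            "sample_id": [s for s, a in zip(sample_ids, amplified) if a],
            "gene": spec.gene,
        }
    )
    subgroup = pd.Series(in_subgroup, index=sample_ids, name="in_subgroup")
    truth = {
        "sample_ids": sample_ids,
        "mutated_samples": set(mutated_ids),
        "subgroup_samples": {s for s, g in zip(sample_ids, in_subgroup) if g},
        "rates": {"p_subgroup": p1, "p_rest": p0},
        "stage_of": stage_of,
    }
    return variants, amp_table, subgroup, truth


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of a simulated log-scale expression matrix.

    ``effect_size`` is the upward shift (in units of ``noise_sd``) applied
    to signature genes in activation-high samples; ``anchor_coupling``
    controls how strongly the anchor gene (PPARG) tracks the latent
    activation state.
    """

    n_genes: int = 500
    n_samples: int = 200
    n_signature_genes: int = 10
    effect_size: float = 2.0
    activation_high_fraction: float = 0.25
    noise_sd: float = 1.0
    anchor_coupling: float = 3.0
    anchor_gene: str = "PPARG"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not (0.0 < self.activation_high_fraction < 1.0):
            raise ValidationError("activation_high_fraction must lie in (0, 1)")
        if self.n_signature_genes > self.n_genes:
            raise ValidationError("n_signature_genes exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


def simulate_expression(
    spec: ExpressionSimSpec,
    seed: int,
    sample_ids: list[str] | None = None,
    high_samples: set | None = None,
):
    """Draw a genes x samples log-expression matrix plus latent truth.

    Baseline values are i.i.d. normal(0, noise_sd); signature genes gain
    ``effect_size * noise_sd`` in activation-high samples, and the anchor
    gene gains ``anchor_coupling * noise_sd`` there.  ``sample_ids`` and
    ``high_samples`` let a caller couple the matrix to an existing cohort
    (shared identifiers and a given latent activation-high set); by
    default both are drawn fresh.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    if sample_ids is not None:
        if len(sample_ids) != spec.n_samples:
            raise ValidationError("sample_ids length must equal n_samples")
        samples = list(sample_ids)
    else:
        samples = [f"T{i:04d}" for i in range(1, spec.n_samples + 1)]
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))

    if high_samples is not None:
        high_idx = np.array(
            [i for i, s in enumerate(samples) if s in high_samples], dtype=int
        )
        if high_idx.size == 0:
            raise ValidationError("high_samples matches no sample identifier")
    else:
        n_high = max(1, round(spec.activation_high_fraction * spec.n_samples))
        high_idx = rng.choice(spec.n_samples, size=n_high, replace=False)
    sig_idx = rng.choice(spec.n_genes, size=spec.n_signature_genes, replace=False)
    values[np.ix_(sig_idx, high_idx)] += spec.effect_size * spec.noise_sd

    anchor = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    anchor[high_idx] += spec.anchor_coupling * spec.noise_sd

    expr = pd.DataFrame(values, index=genes, columns=samples)
    expr.loc[spec.anchor_gene] = anchor
    truth = {
        "signature_genes": {genes[i] for i in sig_idx},
        "high_samples": {samples[i] for i in high_idx},
        "anchor_gene": spec.anchor_gene,
    }
    return expr, truth


# Ideal-helix geometry: 1.5 A rise and 100 degrees of twist per residue.
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
_HELIX_RADIUS = 2.3

# Local atom offsets (A) giving each residue a small heavy-atom cloud.
_ATOM_OFFSETS = (
    ("N", (-0.7, 0.6, -0.5)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (0.9, 0.5, 0.4)),
    ("O", (1.1, 1.6, 0.6)),
    ("CB", (0.4, -1.2, 0.6)),
)


def _helix_residues(n_residues: int, x_shift: float = 0.0) -> list[Residue]:
    residues = []
    for i in range(n_residues):
        theta = math.radians(_HELIX_TWIST_DEG * i)
        cx = _HELIX_RADIUS * math.cos(theta) + x_shift
        cy = _HELIX_RADIUS * math.sin(theta)
        cz = _HELIX_RISE * i
        atoms = tuple(
            Atom(name, (cx + dx, cy + dy, cz + dz))
            for name, (dx, dy, dz) in _ATOM_OFFSETS
        )
        residues.append(Residue(str(i + 1), "ALA", atoms))
    return residues


def _min_inter_chain_distance(chain_a, chain_b) -> float:
    pts_a = np.concatenate([r.coords() for r in chain_a])
    pts_b = np.concatenate([r.coords() for r in chain_b])
    diff = pts_a[:, None, :] - pts_b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def make_toy_heterodimer(
    n_residues_per_chain: int = 20,
    inter_chain_gap: float = 4.0,
    seed: int = 0,
    truth_cutoff: float = 5.0,
):
    """Two parallel ideal poly-alanine helices at a stated closest gap.

    Chain B is chain A translated along x so that the minimum inter-chain
    heavy-atom distance equals ``inter_chain_gap``.  Returns the model and
    a truth record with the brute-force interface sets at ``truth_cutoff``.
    The seed is accepted for interface uniformity; the construction itself
    is deterministic geometry.
    """
    del seed  # geometry is deterministic
    if inter_chain_gap <= 0:
        raise ValidationError("inter_chain_gap must be positive")
    chain_a = _helix_residues(n_residues_per_chain)

    def gap_at(shift: float) -> float:
        return _min_inter_chain_distance(
            chain_a, _helix_residues(n_residues_per_chain, x_shift=shift)
        )

    lo = 2.0 * _HELIX_RADIUS + 2 * 2.0  # past any overlap
    hi = lo + inter_chain_gap + 10.0
    shift = brentq(lambda s: gap_at(s) - inter_chain_gap, lo, hi, xtol=1e-9)
    chain_b = _helix_residues(n_residues_per_chain, x_shift=shift)
    model = StructureModel(chains={"A": chain_a, "B": chain_b})

    # Truth by brute-force double loop, independent of the query code path.
    truth_a, truth_b = set(), set()
    for ra in chain_a:
        for rb in chain_b:
            d = float(np.sqrt(
                ((ra.coords()[:, None, :] - rb.coords()[None, :, :]) ** 2)
                .sum(axis=2)).min())
            if d <= truth_cutoff:
                truth_a.add(ra.res_seq)
                truth_b.add(rb.res_seq)
    truth = {
        "interface_a": truth_a,
        "interface_b": truth_b,
        "cutoff": truth_cutoff,
        "shift": shift,
    }
    return model, truth


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal valid PDB-format file."""
    lines = []
    serial = 1
    for chain_id in sorted(model.chains):
        for res in model.chains[chain_id]:
            for atom in res.atoms:
                x, y, z = atom.coord
                element = atom.name[0]
                lines.append(
                    f"ATOM  {serial:>5} {atom.name:<4}{res.name:>4} "
                    f"{chain_id}{res.number:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5}      {res.name:>3} "
                     f"{chain_id}{res.number:>4}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def bladder_narrative_variants():
    """Deterministic fixture cohort reproducing the published mutation
    narrative in miniature.

    Encodes, in the PPARgamma2 frame: six changes recurrent within the
    sequenced cohorts (T475M the most frequent), E3K seen once in the
    cohort but again in public databases, M280I seen once in bladder plus
    external occurrences, and thirteen further singletons — 21 unique
    changes in all, so that pooling external-database occurrences yields
    eight recurrent mutations.
    """
    iso = "PPARG2"
    cohort_counts = [
        ("T475M", 4, ["MIBC", "NMIBC", "MIBC", "NMIBC"]),
        ("P113S", 2, ["MIBC", "NMIBC"]),
        ("R164W", 2, ["NMIBC", "MIBC"]),
        ("R168K", 2, ["MIBC", "NMIBC"]),
        ("S249L", 2, ["NMIBC", "MIBC"]),
        ("I290M", 2, ["MIBC", "NMIBC"]),
        ("E3K", 1, ["MIBC"]),
        ("M280I", 1, ["MIBC"]),
    ]
    singleton_labels = [
        "A12T", "G45R", "S76F", "L98V", "D122N", "E155K", "V201M",
        "P240L", "H266Y", "K301N", "Q345H", "R425C", "F460L",
    ]
    variants = []
    sample_no = 1
    from .variants import parse_protein_change

    for label, count, stage_list in cohort_counts:
        change = parse_protein_change(label, iso)
        for k in range(count):
            variants.append(
                Variant(
                    sample_id=f"CIT{sample_no:03d}",
                    cohort="CIT",
                    stage=Stage(stage_list[k]),
                    gene="PPARG",
                    change=change,
                    source=Source.COHORT,
                )
            )
            sample_no += 1
    for label in singleton_labels:
        change = parse_protein_change(label, iso)
        variants.append(
            Variant(
                sample_id=f"CIT{sample_no:03d}",
                cohort="CIT",
                stage=Stage("MIBC"),
                gene="PPARG",
                change=change,
                source=Source.COHORT,
            )
        )
        sample_no += 1
    # External-database occurrences: one each for E3K and M280I, plus an
    # extra T475M sighting in another tumor type.
    for label, n in (("E3K", 1), ("M280I", 1), ("T475M", 1)):
        change = parse_protein_change(label, iso)
        for k in range(n):
            variants.append(
                Variant(
                    sample_id=f"DB-{label}-{k}",
                    cohort="COSMIC",
                    stage=Stage("unknown"),
                    gene="PPARG",
                    change=change,
                    source=Source.EXTERNAL_DB,
                )
            )
    return variants
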