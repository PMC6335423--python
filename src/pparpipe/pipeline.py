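"""End-to-end orchestration: simulate or ingest, harmonize, call recurrence,
score activation, test enrichment, and map mutations onto structure.

A run is driven by a single configuration (YAML file or dict); all
randomness flows from one master seed, and every output directory carries
a provenance file with the configuration hash so identical runs are
byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import score as score_mod
from . import simulate as sim
from . import stats as stats_mod
from . import structure as struct_mod
from .variants import (
    DomainMap,
    Source,
    build_lolliplot_table,
    build_oncoprint_matrix,
    call_recurrent,
    pparg2_domain_map,
    read_mutation_table,
    variants_to_frame,
    write_recurrence_table,
)

__all__ = ["RunConfig", "run_pipeline", "load_config", "config_hash"]

SUMMARY_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {
        "simulate": {
            "recurrent_positions": [
                ["PPARG", "T475M", 4],
                ["PPARG", "S249L", 2],
                ["PPARG", "I290M", 2],
            ]
        }
    },
    "expression": {"simulate": {}},
    "structure": {"simulate": {}},
    "recurrence": {"min_count": 2, "pool_external": True},
    "score": {
        "anchor_gene": "PPARG",
        "quartile": 0.25,
        "alpha": 0.05,
        "centering": "gene_mean",
        "threshold_rule": "positive",
    },
    "structure_params": {"chains": ["A", "B"], "cutoff": 5.0},
}


@dataclass
class RunConfig:
    raw: dict = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    # Sections naming a data source: the user's choice replaces the default
    # wholesale (a configured input file must not inherit 'simulate').
    _SOURCE_SECTIONS = frozenset({"cohort", "expression", "structure"})

    def section(self, name: str) -> dict:
        user = self.raw.get(name)
        if name in self._SOURCE_SECTIONS and user is not None:
            return dict(user)
        merged = dict(DEFAULT_CONFIG.get(name) or {})
        if user is not None:
            merged.update(user)
        return merged

    def has_section(self, name: str) -> bool:
        if name in self.raw:
            return self.raw[name] is not None
        return name in DEFAULT_CONFIG


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run configuration must be a mapping")
    return RunConfig(raw)


def _canonical(obj):
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(_canonical(config.raw).encode()).hexdigest()[:16]


def _domain_map(config: RunConfig) -> DomainMap:
    section = config.raw.get("domains")
    if not section:
        return pparg2_domain_map()
    return DomainMap(
        gene=section.get("gene", "PPARG"),
        isoform=section.get("isoform", "PPARG2"),
        domains=tuple((d["name"], int(d["start"]), int(d["end"]))
                      for d in section["domains"]),
        landmarks=tuple((l["name"], int(l["position"]))
                        for l in section.get("landmarks", [])),
        protein_length=section.get("protein_length"),
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all configured stages in dependency order.

    Returns the run report (also written as ``summary.json``): stage
    statuses, output paths, and the key numbers each stage produced.
    Stages without inputs (e.g. no expression data) are reported skipped,
    mirroring cohorts for which no transcriptomic data were available.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = config.seed
    report: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config_hash": chash,
        "seed": seed,
        "stages": {},
        "outputs": {},
        "summary": {},
    }
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            _finalize(out, report, log_lines)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report["stages"][name]["wall_s"] = round(time.perf_counter() - t0, 4)

    state: dict = {}

    # --- cohort ---------------------------------------------------------
    def stage_cohort():
        section = config.section("cohort")
        if "simulate" in section:
            spec_kwargs = dict(section["simulate"])
            if "recurrent_positions" in spec_kwargs:
                from .variants import parse_protein_change

                spec_kwargs["recurrent_positions"] = tuple(
                    (gene, parse_protein_change(
                        label, spec_kwargs.get("isoform", "PPARG2")), int(count))
                    for gene, label, count in spec_kwargs["recurrent_positions"]
                )
            if "stage_fractions" in spec_kwargs:
                spec_kwargs["stage_fractions"] = tuple(
                    (str(s), float(p)) for s, p in spec_kwargs["stage_fractions"]
                )
            spec = sim.CohortSimSpec(**spec_kwargs)
            variants, amp_table, subgroup, truth = sim.simulate_cohort(
                spec, seed=seed
            )
            state["all_samples"] = truth["sample_ids"]
            state["subgroup_truth"] = truth["subgroup_samples"]
            log("cohort", f"simulated {spec.n_samples} samples, "
                          f"{len(variants)} variant observations")
        elif "mutations" in section:
            variants = read_mutation_table(section["mutations"])
            amp_path = section.get("amplifications")
            amp_table = (
                pd.read_csv(amp_path, sep="\t", dtype=str)
                if amp_path
                else pd.DataFrame(columns=["sample_id", "gene"])
            )
            samples = section.get("all_samples")
            if samples:
                state["all_samples"] = list(
                    pd.read_csv(samples, sep="\t", header=None)[0]
                )
            else:
                state["all_samples"] = sorted(
                    {v.sample_id for v in variants if v.source is Source.COHORT}
                    | set(amp_table["sample_id"])
                )
            log("cohort", f"read {len(variants)} variant observations")
        else:
            raise ConfigError("cohort section needs 'simulate' or 'mutations'")
        state["variants"] = variants
        state["amplifications"] = list(
            amp_table.itertuples(index=False, name=None)
        )
        mut_path = out / "mutations.tsv"
        _write_tsv(variants_to_frame(variants), mut_path)
        report["outputs"]["mutations"] = mut_path.name
        report["stages"]["cohort"] = {"status": "ok",
                                      "n_observations": len(variants)}

    # --- recurrence -----------------------------------------------------
    def stage_recurrence():
        section = config.section("recurrence")
        records = call_recurrent(
            state["variants"],
            min_count=int(section.get("min_count", 2)),
            pool_external=bool(section.get("pool_external", True)),
        )
        state["records"] = records
        rec_path = out / "recurrence.tsv"
        write_recurrence_table(records, rec_path)
        dm = _domain_map(config)
        lolli = build_lolliplot_table(
            [r for r in records if r.is_recurrent and r.gene == dm.gene], dm
        )
        lolli_path = out / "lolliplot.tsv"
        _write_tsv(lolli, lolli_path)
        report["outputs"]["recurrence"] = rec_path.name
        report["outputs"]["lolliplot"] = lolli_path.name
        n_rec = sum(r.is_recurrent for r in records)
        report["stages"]["recurrence"] = {
            "status": "ok",
            "n_distinct_changes": len(records),
            "n_recurrent": n_rec,
        }
        report["summary"]["n_recurrent"] = n_rec
        log("recurrence", f"{n_rec} recurrent of {len(records)} distinct changes")

    # --- activation score ----------------------------------------------
    def stage_score():
        if not config.has_section("expression"):
            report["stages"]["score"] = {
                "status": "skipped",
                "reason": "no transcriptomic data configured",
            }
            log("score", "skipped: no transcriptomic data")
            return
        section = config.section("expression")
        params = config.section("score")
        if "simulate" in section:
            spec_kwargs = dict(section["simulate"])
            spec_kwargs.setdefault("n_samples", len(state["all_samples"]))
            spec = sim.ExpressionSimSpec(**spec_kwargs)
            expr, truth = sim.simulate_expression(
                spec,
                seed=seed + 1,
                sample_ids=state["all_samples"],
                high_samples=state.get("subgroup_truth"),
            )
            seed_genes = sorted(truth["signature_genes"]) + [
                g for g in expr.index[:10] if g not in truth["signature_genes"]
            ]
            state["expression_truth"] = truth
        elif "matrix" in section:
            expr = pd.read_csv(section["matrix"], sep="\t", index_col=0)
            with open(section["seed_genes"]) as fh:
                seed_genes = [line.strip() for line in fh if line.strip()]
        else:
            report["stages"]["score"] = {
                "status": "skipped",
                "reason": "no transcriptomic data configured",
            }
            log("score", "skipped: no transcriptomic data")
            return
        signature = score_mod.refine_signature(
            expr,
            anchor_gene=params["anchor_gene"],
            seed_genes=seed_genes,
            quartile=float(params["quartile"]),
            alpha=float(params["alpha"]),
        )
        result = score_mod.score_samples(expr, signature, params["centering"])
        high = score_mod.classify_activation(result, params["threshold_rule"])
        state["score_result"] = result
        state["activation_high"] = set(high[high].index)
        state["score_samples"] = list(expr.columns)
        scores_df = pd.DataFrame(
            {
                "sample_id": result.scores.index,
                "score": result.scores.to_numpy(),
                "activation_high": [str(v).lower() for v in high.to_numpy()],
            }
        )
        scores_path = out / "scores.tsv"
        _write_tsv(scores_df, scores_path)
        sig_rows = sorted(signature.adjusted_p.items())
        sig_df = pd.DataFrame(
            {
                "gene": [g for g, _ in sig_rows],
                "retained": [
                    str(g in signature.refined_genes).lower() for g, _ in sig_rows
                ],
                "adjusted_p": [p for _, p in sig_rows],
            }
        )
        sig_path = out / "signature.tsv"
        _write_tsv(sig_df, sig_path)
        report["outputs"]["scores"] = scores_path.name
        report["outputs"]["signature"] = sig_path.name
        report["stages"]["score"] = {
            "status": "ok",
            "n_refined_genes": len(signature.refined_genes),
            "n_activation_high": int(high.sum()),
        }
        report["summary"]["n_refined_genes"] = len(signature.refined_genes)
        report["summary"]["n_activation_high"] = int(high.sum())
        log("score", f"{len(signature.refined_genes)} genes retained; "
                     f"{int(high.sum())} activation-high samples")

    # --- oncoprint ------------------------------------------------------
    def stage_oncoprint():
        if "score_result" in state:
            order = score_mod.sort_by_score(state["score_result"])
            extra = [s for s in state["all_samples"] if s not in set(order)]
            order = order + sorted(extra)
        else:
            order = sorted(state["all_samples"])
        cohort_variants = [
            v for v in state["variants"] if v.source is Source.COHORT
        ]
        matrix = build_oncoprint_matrix(
            cohort_variants, state["amplifications"], order
        )
        path = out / "oncoprint.tsv"
        _write_tsv(matrix, path, index=True)
        report["outputs"]["oncoprint"] = path.name
        report["stages"]["oncoprint"] = {
            "status": "ok",
            "n_samples": matrix.shape[1],
            "n_genes": matrix.shape[0],
        }
        log("oncoprint", f"{matrix.shape[0]} genes x {matrix.shape[1]} samples")

    # --- enrichment -----------------------------------------------------
    def stage_enrichment():
        if "activation_high" not in state:
            report["stages"]["enrichment"] = {
                "status": "skipped",
                "reason": "no activation classification available",
            }
            log("enrichment", "skipped: no activation classification")
            return
        all_samples = state["all_samples"]
        mutated = {
            v.sample_id
            for v in state["variants"]
            if v.source is Source.COHORT and v.sample_id in set(all_samples)
        }
        amplified = {s for s, _ in state["amplifications"]}
        high = state["activation_high"]
        rows = []
        tests = [("mutation", mutated), ("amplification", amplified)]
        for name, altered in tests:
            res = stats_mod.subgroup_enrichment(altered, high, all_samples)
            t = res.table
            rows.append(
                {
                    "alteration": name,
                    "group": "activation_high",
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "odds_ratio": res.odds_ratio,
                    "p_two_sided": res.p_two_sided,
                    "direction": res.direction.value,
                }
            )
        enr = pd.DataFrame(rows)
        path = out / "enrichment.tsv"
        _write_tsv(enr, path)
        report["outputs"]["enrichment"] = path.name
        report["stages"]["enrichment"] = {"status": "ok", "n_tests": len(rows)}
        report["summary"]["enrichment_p_mutation"] = float(
            enr.loc[enr["alteration"] == "mutation", "p_two_sided"].iloc[0]
        )
        log("enrichment", f"{len(rows)} exact tests")

    # --- structure ------------------------------------------------------
    def stage_structure():
        if not config.has_section("structure"):
            report["stages"]["structure"] = {
                "status": "skipped",
                "reason": "no structure configured",
            }
            log("structure", "skipped: no structure input")
            return
        section = config.section("structure")
        params = config.section("structure_params")
        if "simulate" in section:
            sim_kwargs = dict(section["simulate"])
            model, truth = sim.make_toy_heterodimer(seed=seed + 2, **sim_kwargs)
            pdb_path = out / "toy_heterodimer.pdb"
            sim.write_pdb(model, pdb_path)
            report["outputs"]["structure_pdb"] = pdb_path.name
        elif "pdb" in section:
            model = struct_mod.read_structure(section["pdb"])
        else:
            report["stages"]["structure"] = {
                "status": "skipped",
                "reason": "no structure configured",
            }
            log("structure", "skipped: no structure input")
            return
        chain_a, chain_b = params["chains"]
        iface = struct_mod.interface_residues(
            model, chain_a, chain_b, cutoff=float(params["cutoff"])
        )
        payload = {
            "pair": list(iface.pair),
            "cutoff": iface.cutoff,
            "interface_residues_a": sorted(iface.interface_residues_a,
                                           key=lambda r: int(r)),
            "interface_residues_b": sorted(iface.interface_residues_b,
                                           key=lambda r: int(r)),
            "config_hash": chash,
        }
        path = out / "interface.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        report["outputs"]["interface"] = path.name
        report["stages"]["structure"] = {
            "status": "ok",
            "n_interface_a": len(iface.interface_residues_a),
            "n_interface_b": len(iface.interface_residues_b),
        }
        report["summary"]["n_interface_residues"] = (
            len(iface.interface_residues_a) + len(iface.interface_residues_b)
        )
        log("structure", f"interface: {len(iface.interface_residues_a)}+"
                         f"{len(iface.interface_residues_b)} residues")

    for name, fn in [
        ("cohort", stage_cohort),
        ("recurrence", stage_recurrence),
        ("score", stage_score),
        ("oncoprint", stage_oncoprint),
        ("enrichment", stage_enrichment),
        ("structure", stage_structure),
    ]:
        run_stage(name, fn)

    _finalize(out, report, log_lines)
    return report


def _finalize(out: Path, report: dict, log_lines: list[str]) -> None:
    # wall times vary between runs; the summary on disk must not
    persisted = json.loads(_canonical(report))
    for stage in persisted["stages"].values():
        stage.pop("wall_s", None)
    (out / "summary.json").write_text(
        json.dumps(persisted, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
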