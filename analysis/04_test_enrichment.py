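#!/usr/bin/env python
"""Exact tests: are mutations and amplifications enriched in
activation-high tumors, and are the two alteration types mutually
exclusive?

Consumes the simulated cohort (01) and the activation classification (03).
"""

import argparse
from pathlib import Path

import pandas as pd

from pparpipe.stats import cooccurrence_test, subgroup_enrichment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--scores", type=Path, default=Path("results/score"))
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    muts = pd.read_csv(args.sim / "mutations.tsv", sep="\t", dtype=str)
    amps = pd.read_csv(args.sim / "amplifications.tsv", sep="\t", dtype=str)
    scores = pd.read_csv(args.scores / "scores.tsv", sep="\t", dtype=str)

    all_samples = list(scores["sample_id"])
    mutated = set(muts["sample_id"]) & set(all_samples)
    amplified = set(amps["sample_id"]) & set(all_samples)
    high = set(scores.loc[scores["activation_high"] == "true", "sample_id"])

    rows = []
    for name, altered in (("mutation", mutated), ("amplification", amplified)):
        res = subgroup_enrichment(altered, high, all_samples)
        t = res.table
        rows.append({"test": f"{name}_vs_activation_high",
                     "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "odds_ratio": res.odds_ratio,
                     "p_two_sided": res.p_two_sided,
                     "direction": res.direction.value})
        print(f"{name} vs activation-high: OR={res.odds_ratio:.3g} "
              f"p={res.p_two_sided:.3g} ({res.direction.value})")
    res = cooccurrence_test(mutated, amplified, all_samples)
    t = res.table
    rows.append({"test": "mutation_vs_amplification",
                 "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                 "odds_ratio": res.odds_ratio,
                 "p_two_sided": res.p_two_sided,
                 "direction": res.direction.value})
    print(f"mutation vs amplification: OR={res.odds_ratio:.3g} "
          f"p={res.p_two_sided:.3g} ({res.direction.value})")

    pd.DataFrame(rows).to_csv(args.out / "enrichment.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
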