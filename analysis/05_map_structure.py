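#!/usr/bin/env python
"""Map recurrent LBD mutations onto a heterodimer structure.

Reads the toy two-chain structure written by 01_simulate_cohort.py (or any
PDB file passed with --pdb, e.g. a deposited heterodimer structure),
reports the chain A/B interface at 5 A, and annotates queried mutation
positions with interface membership and intra-chain contact partners.
"""

import argparse
import json
from pathlib import Path

from pparpipe.structure import (
    interface_residues,
    map_mutations_to_structure,
    read_structure,
)
from pparpipe.variants import parse_protein_change


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--pdb", type=Path,
                    default=Path("results/sim/toy_heterodimer.pdb"))
    ap.add_argument("--chains", default="A,B")
    ap.add_argument("--cutoff", type=float, default=5.0)
    ap.add_argument("--positions", default="5,12",
                    help="comma-separated chain-A residue numbers to annotate")
    ap.add_argument("--out", type=Path, default=Path("results/structure"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    model = read_structure(args.pdb)
    chain_a, chain_b = args.chains.split(",")
    iface = interface_residues(model, chain_a, chain_b, cutoff=args.cutoff)
    print(f"interface at {args.cutoff} A: "
          f"{sorted(iface.interface_residues_a, key=int)} (chain {chain_a}) / "
          f"{sorted(iface.interface_residues_b, key=int)} (chain {chain_b})")

    mutations = [("GENE_A", parse_protein_change(f"A{p}V", "PPARG2"))
                 for p in args.positions.split(",")]
    annotations = map_mutations_to_structure(
        mutations, model, {"GENE_A": chain_a},
        partner_of_chain={chain_a: chain_b},
        interface_cutoff=args.cutoff,
    )
    payload = {
        "cutoff": args.cutoff,
        "interface_a": sorted(iface.interface_residues_a, key=int),
        "interface_b": sorted(iface.interface_residues_b, key=int),
        "mutations": [
            {
                "position": ann.structure_position,
                "resolved": ann.resolved,
                "in_interface": ann.in_interface,
                "n_contact_partners": len(ann.partners),
            }
            for ann in annotations
        ],
    }
    (args.out / "interface.json").write_text(
        json.dumps(payload, indent=2) + "\n")
    for ann in annotations:
        status = "in interface" if ann.in_interface else "not in interface"
        print(f"position {ann.structure_position}: {status}, "
              f"{len(ann.partners)} contact partner(s)")


if __name__ == "__main__":
    main()
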