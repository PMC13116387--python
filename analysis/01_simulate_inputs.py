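"""Generate the synthetic study inputs every later stage consumes.

Writes a 171-compound screening library, a toy protein–ligand complex with
planted contacts, and a 311-node scale-free PPI network with a planted hub
under results/synthetic/, each with its ground truth.
"""

import json
from pathlib import Path

from gradescreen.compound_io import write_library_csv
from gradescreen.synthetic_data import (
    ComplexSpec,
    LibrarySpec,
    NetworkSpec,
    generate_compound_library,
    generate_ppi_network,
    generate_toy_complex,
)

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    lib = generate_compound_library(LibrarySpec(n=171, seed=SEED))
    write_library_csv(lib, OUT / "library.csv")
    print(f"library: {len(lib)} compounds -> {OUT / 'library.csv'}")

    spec = ComplexSpec(n_hbond=2, n_salt=1, n_hydrophobic=2, n_pi=1, seed=SEED)
    pdb_text, truth = generate_toy_complex(spec)
    (OUT / "complex.pdb").write_text(pdb_text)
    (OUT / "complex_truth.json").write_text(
        json.dumps([t.__dict__ for t in truth], indent=2)
    )
    print(f"complex: {len(truth)} planted contacts -> {OUT / 'complex.pdb'}")

    tsv, hub = generate_ppi_network(NetworkSpec(n=311, seed=SEED))
    (OUT / "network.tsv").write_text(tsv)
    (OUT / "network_truth.json").write_text(json.dumps({"hub": hub}, indent=2))
    print(f"network: 311 genes, planted hub {hub} -> {OUT / 'network.tsv'}")


if __name__ == "__main__":
    main()
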