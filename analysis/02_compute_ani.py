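"""All-vs-all fragment ANI for each simulated scenario.

Reads results/data/<scenario>/, writes results/ani/<scenario>_pairs.tsv
(query_id, ref_id, ani, shared_fraction, n_fragments, n_bidirectional;
the longer genome of each pair serves as the reference).
"""

from pathlib import Path

import numpy as np

from anigap import ani, io
from anigap.simulate import read_species

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    outdir = RESULTS / "ani"
    outdir.mkdir(parents=True, exist_ok=True)
    for scenario in ("gapped", "gapless", "clonal"):
        indir = RESULTS / "data" / scenario
        if not indir.exists():
            print(f"{scenario}: no data (run 01_simulate_species.py first)")
            continue
        genomes = read_species(indir)
        pairs = ani.pair_table(genomes)
        io.write_pair_table(pairs, outdir / f"{scenario}_pairs.tsv")
        vals = np.array([p.ani for p in pairs if p.ani is not None])
        sf = np.array([p.shared_fraction for p in pairs])
        print(
            f"{scenario}: {len(pairs)} pairs, ANI {vals.min():.2f}-{vals.max():.2f}, "
            f"mean shared genome fraction {sf.mean():.2f}"
        )


if __name__ == "__main__":
    main()
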