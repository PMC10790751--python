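"""Gene-content diversity: shared-gene decline and mobile-gene enrichment.

For the gapped species: shared gene fraction per pair (against ANI), and
the two-proportion z-test for enrichment of hypothetical/mobile genes
among genes not shared between very close pairs (ANI > 99.8) relative to
more divergent pairs.

Writes results/genes/gene_shares.tsv and enrichment.json.
"""

from pathlib import Path

import pandas as pd

from anigap import enrich, io
from anigap.ani import shared_gene_fraction
from anigap.simulate import read_species

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    outdir = RESULTS / "genes"
    outdir.mkdir(parents=True, exist_ok=True)
    from importlib import import_module
    load_pairs = import_module("04_delineate_units").load_pairs  # same thin helper

    pairs = load_pairs(RESULTS / "ani" / "gapped_pairs.tsv")
    genomes = {g.genome_id: g for g in read_species(RESULTS / "data" / "gapped")}

    shares = {}
    rows = []
    for p in pairs:
        if p.ani is None:
            continue
        key = tuple(sorted((p.query_id, p.ref_id)))
        gs = shared_gene_fraction(genomes[key[0]], genomes[key[1]])
        shares[key] = gs
        rows.append({"genome_a": key[0], "genome_b": key[1], "ani": p.ani,
                     "shared_gene_fraction": gs.shared_gene_fraction,
                     "n_orthologs": len(gs.orthologs)})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "gene_shares.tsv", sep="\t", index=False)
    close = df[df.ani > 99.8]
    div = df[(df.ani >= 96) & (df.ani <= 99.8)]
    print(f"shared gene fraction: {close.shared_gene_fraction.mean():.3f} for ANI>99.8 "
          f"({len(close)} pairs) vs {div.shared_gene_fraction.mean():.3f} for 96-99.8 "
          f"({len(div)} pairs)")

    res = enrich.enrichment_test(pairs, shares)
    io.write_json(
        {
            "close": vars(res.close), "divergent": vars(res.divergent),
            "pooled": res.pooled, "z": res.z, "p_value": res.p_value,
        },
        outdir / "enrichment.json",
    )
    print(f"mobile fraction of non-shared genes: close {res.close.proportion:.3f} "
          f"vs divergent {res.divergent.proportion:.3f}; z={res.z:.2f}, p={res.p_value:.2e}")


if __name__ == "__main__":
    main()
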