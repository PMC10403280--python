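#!/usr/bin/env python
"""Filter the simulated screens for statistically enriched pairs.

Pools the two late rounds of each screen and applies the upper-tail
hypergeometric test at p < 0.05, writing the enriched pair sets and
per-position frequency matrices under results/.
"""

from pathlib import Path

from coevoscreen.pair_enrichment import filter_pairs, position_frequency_matrix
from coevoscreen.screen_simulator import read_tables

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for label in ("restricted", "expanded"):
        tables = read_tables(OUT / f"screen_{label}.tsv")
        enriched = filter_pairs(tables, ["round4", "round5"], alpha=0.05)
        enriched.write_tsv(OUT / f"enriched_{label}.tsv")
        print(f"{label}: {len(enriched.df)} of {len(enriched.all_pairs)} pooled "
              f"pairs enriched at p < 0.05")
        for chain in "AB":
            pfm = position_frequency_matrix(tables[-1], chain)
            pfm.write_tsv(OUT / f"pfm_{label}_{chain}.tsv")
            consensus = "".join(pfm.df.idxmax())
            print(f"  final-round chain {chain} consensus: {consensus}")


if __name__ == "__main__":
    main()
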