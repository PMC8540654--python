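#!/usr/bin/env python
"""Indicator taxa of the BC-load categories: Kruskal-Wallis screen plus
bootstrapped LDA effect size at genus, family, order and class rank, then
a check of the reported genera against the planted simulation truth.

Writes results/indicator_taxa.tsv.
"""
import json
from pathlib import Path

import pandas as pd

from phylloplane import filter_samples, find_indicators, remove_taxa_by_lineage
from phylloplane import io as pio

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "campaign"
OUT = ROOT / "results"
SEED = 5
RANK_LETTER = {"genus": "g", "family": "f", "order": "o", "class": "c"}


def main() -> None:
    if not DATA.exists():
        raise SystemExit("run analysis/02_simulate_campaign.py first")
    OUT.mkdir(exist_ok=True)
    table = pio.read_asv_table(DATA / "asv_counts.tsv", DATA / "taxonomy.tsv")
    metadata = pio.read_metadata(DATA / "metadata.tsv")
    table = remove_taxa_by_lineage(filter_samples(table, 500))
    meta = metadata.loc[table.sample_ids]

    frames = []
    for rank in ("genus", "family", "order", "class"):
        res = find_indicators(table, meta["bc_category"], rank=rank, seed=SEED)
        t = res.table.reset_index()
        t["rank_letter"] = RANK_LETTER[rank]
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)[
        ["taxon", "rank_letter", "category", "p", "lda_score"]
    ].sort_values(["rank_letter", "lda_score"], ascending=[True, False])
    out.to_csv(OUT / "indicator_taxa.tsv", sep="\t", index=False)
    print(out.round(3).to_string(index=False))

    truth = json.loads((DATA / "community_truth.json").read_text())
    taxonomy = table.taxonomy
    planted = {
        taxonomy.loc[t, "genus"]: cat
        for t, cat in truth["bc_indicator_taxa"].items()
        if t in taxonomy.index
    }
    genus_hits = out.query("rank_letter == 'g'").set_index("taxon")
    recovered = [g for g in planted if g in genus_hits.index]
    correct = [g for g in recovered if genus_hits.loc[g, "category"] == planted[g]]
    print(
        f"\nplanted genus indicators recovered: {len(recovered)}/{len(planted)} "
        f"({len(correct)} with the planted category)"
    )


if __name__ == "__main__":
    main()
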