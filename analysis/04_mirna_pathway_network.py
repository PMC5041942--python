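"""Build the bipartite miRNA-pathway crosstalk network and call hub miRNAs.

Each miRNA's inversely correlated target set is tested against every
pathway with the cumulative hypergeometric law; relations with p < 0.05
become edges.  Hubs are the inclusive top 15% of miRNAs by degree.
"""

import pandas as pd

from common import analysis_config, RESULTS
from mircross.pipeline import run_stage
from mircross.synthdata import GroundTruth


def main() -> None:
    cfg = analysis_config()
    run_stage("mirpath", cfg)
    edges = pd.read_csv(RESULTS / "mirna_pathway_edges.tsv", sep="\t")
    hubs = pd.read_csv(RESULTS / "hubs.tsv", sep="\t")
    truth = GroundTruth.from_json(RESULTS / "ground_truth.json")
    print(f"network: {edges['mirna_id'].nunique()} miRNAs, "
          f"{edges['pathway_id'].nunique()} pathways, {len(edges)} edges")
    print(f"hub miRNAs ({len(hubs)}): {', '.join(hubs['mirna_id'].head(9))}"
          + (" ..." if len(hubs) > 9 else ""))
    edge_set = set(zip(edges["mirna_id"], edges["pathway_id"]))
    hits = total = 0
    for mirna, pws in truth.planted_enriched_pathways.items():
        for pw in pws:
            total += 1
            hits += (mirna, pw) in edge_set
    print(f"planted miRNA-pathway relation recovery: {100 * hits / total:.1f}%")


if __name__ == "__main__":
    main()
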