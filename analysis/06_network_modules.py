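"""Detect network modules: maximal bicliques and k-clique communities.

Biclique modules pair a miRNA set with the pathway set it jointly
regulates; clique-percolation (k=3) communities of the crosstalk network
are the dense pathway modules; the core module is the community around the
highest-degree pathway plus its bridge pathways.
"""

import pandas as pd

from common import analysis_config, RESULTS
from mircross.pipeline import run_stage


def main() -> None:
    cfg = analysis_config()
    run_stage("modules", cfg)
    bic = pd.read_csv(RESULTS / "biclique_modules.tsv", sep="\t")
    com = pd.read_csv(RESULTS / "clique_communities.tsv", sep="\t")
    core = pd.read_csv(RESULTS / "core_module.tsv", sep="\t")
    n_modules = bic["module_id"].nunique() if len(bic) else 0
    print(f"biclique modules: {n_modules}")
    if n_modules:
        sizes = bic.groupby(["module_id", "side"]).size().unstack(fill_value=0)
        largest = sizes.sum(axis=1).idxmax()
        print(f"largest module ({largest}): "
              f"{sizes.loc[largest].get('miRNA', 0)} miRNAs x "
              f"{sizes.loc[largest].get('pathway', 0)} pathways")
    print(f"clique-percolation communities (k={cfg.clique_k}): "
          f"{com['community_id'].nunique() if len(com) else 0}")
    if len(core):
        anchor = core["anchor"].iloc[0]
        in_comm = core["in_community"].sum()
        print(f"core module around {anchor}: {in_comm} community pathways, "
              f"{len(core) - in_comm} bridge pathways")


if __name__ == "__main__":
    main()
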