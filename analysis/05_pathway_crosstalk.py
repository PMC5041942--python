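"""Score pathway-pathway crosstalk with Fisher's method over PPI edges.

Candidate pathways come from enrichment of the grade- and direction-split
target-gene unions; every candidate pair is scored by summing
-2(ln P(a) + ln P(b) + ln P(a,b)) over PPI edges linking their differential
genes, with significance from 1000 gene-set resamplings.  Reports recovery
of the planted crosstalk pairs among the scored candidates.
"""

import pandas as pd

from common import analysis_config, RESULTS
from mircross.pipeline import run_stage
from mircross.synthdata import GroundTruth


def main() -> None:
    cfg = analysis_config()
    run_stage("crosstalk", cfg)
    table = pd.read_csv(RESULTS / "crosstalk_pairs.tsv", sep="\t")
    labels = pd.read_csv(RESULTS / "crosstalk_pathways.tsv", sep="\t")
    truth = GroundTruth.from_json(RESULTS / "ground_truth.json")
    sig = table[table["perm_p"] < cfg.crosstalk_threshold]
    print(f"candidate pathways: {len(labels)}; scored pairs: {len(table)}; "
          f"significant crosstalk edges: {len(sig)}")
    planted = {frozenset(p) for p in truth.planted_crosstalk_pairs}
    scored_keys = {frozenset((a, b))
                   for a, b in zip(table["pathway_i"], table["pathway_j"])}
    sig_keys = {frozenset((a, b))
                for a, b in zip(sig["pathway_i"], sig["pathway_j"])}
    testable = planted & scored_keys
    print(f"planted pairs among candidates: {len(testable)} of {len(planted)}")
    if testable:
        print(f"planted pairs significant: {len(testable & sig_keys)} of {len(testable)}")


if __name__ == "__main__":
    main()
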