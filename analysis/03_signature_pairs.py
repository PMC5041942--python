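"""Select signature miRNA-target pairs by inverse correlation.

A pair survives when it is predicted, both partners are differential with
opposite directions, and Pearson r <= -0.4 with p < 0.05 over grade II plus
the contrast's case samples.  Reports planted-couple recovery and the decoy
false-positive rate.
"""

import pandas as pd

from common import analysis_config, RESULTS
from mircross.pipeline import run_stage
from mircross.synthdata import GroundTruth


def main() -> None:
    cfg = analysis_config()
    run_stage("pairs", cfg)
    pairs = pd.read_csv(RESULTS / "signature_pairs.tsv", sep="\t")
    truth = GroundTruth.from_json(RESULTS / "ground_truth.json")
    for contrast, grp in pairs.groupby("contrast"):
        print(f"{contrast}: {len(grp)} pairs, {grp['mirna_id'].nunique()} miRNAs, "
              f"{grp['gene_id'].nunique()} genes")
        planted = set(truth.planted_pairs[contrast])
        got = set(zip(grp["mirna_id"], grp["gene_id"]))
        print(f"  planted recovery: {100 * len(got & planted) / len(planted):.1f}%")
    decoys = set(truth.decoy_pairs)
    got_all = set(zip(pairs["mirna_id"], pairs["gene_id"]))
    print(f"decoy false positives: {100 * len(got_all & decoys) / len(decoys):.1f}% "
          f"of {len(decoys)} decoys")


if __name__ == "__main__":
    main()
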