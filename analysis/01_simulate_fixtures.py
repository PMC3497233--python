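"""Generate the frozen synthetic inputs for the downstream analyses.

Writes the default fixture set — 21 gene trees on 16 taxa with one
planted incongruent gene, paired two-model tree sets (exchangeable null
and 3x-noise), and three 8-taxon alignments (homogeneous,
composition-shifted, saturated) — to data/fixtures/, and prints what was
planted so later steps can be checked against the ground truth.
"""

import json
from pathlib import Path

from treecongruence.synthetic_data import write_default_fixtures

OUT = Path(__file__).resolve().parents[1] / "data" / "fixtures"


def main():
    write_default_fixtures(OUT)
    truth = json.loads((OUT / "ground_truth.json").read_text())
    cfg = truth["gene_trees"]["config"]
    print(f"fixtures written to {OUT}")
    print(f"gene-tree set: {cfg['gene_count']} genes on {cfg['taxon_count']} taxa, "
          f"Poisson({cfg['nni_moves']}) NNI moves, lognormal sigma {cfg['length_noise_sigma']}")
    print(f"planted incongruent gene(s): {truth['gene_trees']['outlier_names']}")
    print("paired-model sets: null (multiplier 1) and 3x noise; "
          "alignments: homogeneous, shifted, saturated")


if __name__ == "__main__":
    main()
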