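"""Apply the degradation reference filter and pick major/minor TSS pairs.

Reports how many TSSs the 20% flanking-region rule removes, and the
proximal/promoter split of the selected pairs.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import RUN_DIR, pipeline_config, publish  # noqa: E402

import pandas as pd  # noqa: E402

from alttss.pipeline import stage_filter  # noqa: E402


def main() -> None:
    stage_filter(pipeline_config(), RUN_DIR)
    info = json.loads((RUN_DIR / "filter.json").read_text())
    pairs = pd.read_csv(RUN_DIR / "gated_pairs.tsv", sep="\t")
    publish("reference_filter.tsv")
    publish("gene_pairs.tsv")
    publish("gated_pairs.tsv")
    print(f"curated TSSs: {info['n_tss_curated']}; surviving the 20% filter: "
          f"{info['n_tss_surviving']} "
          f"(removed {100 * info['filter_removed_fraction']:.1f}%)")
    print(f"TSSs past the 100-molecule gate: {info['n_tss_gated']}; "
          f"major/minor pairs: {info['n_gene_pairs']}; "
          f"past the 0.3 molecules/cell/TSS gate: {info['n_pairs_expression_gated']}")
    if len(pairs):
        print("pair classes:", pairs["pair_class"].value_counts().to_dict())


if __name__ == "__main__":
    main()
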