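"""Run the ratio-based usage statistics and assemble the final report.

Reports the per-cell binomial deviation rates (and the most bimodal gene),
differential TSS usage between the two cell types, and the ratio-group
differential-expression screen.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import RUN_DIR, pipeline_config, publish  # noqa: E402

from alttss.pipeline import stage_report, stage_usagetest  # noqa: E402


def main() -> None:
    cfg = pipeline_config()
    stage_usagetest(cfg, RUN_DIR)
    stage_report(cfg, RUN_DIR)
    out = json.loads((RUN_DIR / "usage.json").read_text())
    publish("binomial_deviation.tsv")
    publish("differential_usage.tsv")
    publish("summary.json", "study_summary.json")
    if (RUN_DIR / "ratio_group_de.tsv").exists():
        publish("ratio_group_de.tsv")
    print(f"mean % of cells deviating from the population TSS ratio: "
          f"{out['mean_percent_deviating']:.1f}%")
    top = out.get("most_bimodal_gene")
    if top:
        print(f"most bimodal gene: {top['gene_id']} "
              f"({top['percent_deviating']:.1f}% of cells deviating)")
    de = out.get("ratio_group_de")
    if de:
        print(f"ratio-group DE: {de['n_significant']}/{de['n_tested']} significant "
              f"({de['n_significant_fc']} with fold change > 2)")
    du = out["differential_usage"]
    print(f"differential usage between cell types: {du['n_flagged']}/{du['n_tested']} "
          f"flagged: {du['flagged_genes']}")
    print(f"full summary: results/study_summary.json")


if __name__ == "__main__":
    main()
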