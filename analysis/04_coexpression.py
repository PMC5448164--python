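"""Measure major/minor TSS co-expression across single cells.

Reports the mean pair correlation in counts and after rpk normalization,
the correlation-vs-expression regression, and the distance/orientation
group comparisons.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import RUN_DIR, pipeline_config, publish  # noqa: E402

from alttss.pipeline import stage_coexpress  # noqa: E402


def main() -> None:
    stage_coexpress(pipeline_config(), RUN_DIR)
    out = json.loads((RUN_DIR / "coexpression.json").read_text())
    publish("pair_correlations.tsv")
    publish("major_preference_hist.tsv")
    publish("whole_gene_vs_major_tss.tsv")
    if (RUN_DIR / "pair_correlations_rpk.tsv").exists():
        publish("pair_correlations_rpk.tsv")
    print(f"mean pair correlation (counts): {out['mean_pair_r_counts']:.3f}")
    if "mean_pair_r_rpk" in out:
        print(f"mean pair correlation (rpk, {out['n_cells_rpk']} gated cells): "
              f"{out['mean_pair_r_rpk']:.3f}")
    fit = out.get("r_vs_expression")
    if fit:
        print(f"r vs expression: slope {fit['slope']:.4f} "
              f"(p={fit['p_value']:.3g}, n={fit['n_genes']})")
    pc = out.get("pair_class")
    if pc:
        groups = {k: f"{v['mean_r']:.2f} (n={v['n']})" for k, v in pc["groups"].items()}
        print(f"proximal vs promoter mean r: {groups}; p={pc['p_value']}")
    print(f"genes expressing almost only the major TSS: "
          f"{100 * out['major_preference_ge_0.9_fraction']:.0f}%")


if __name__ == "__main__":
    main()
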