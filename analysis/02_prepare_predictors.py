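"""Derive the vegetation-index layers and screen predictors for
collinearity with iterated variance inflation factors.

Writes results/vif_report.csv (one row per predictor per round) and
prints the retained predictor set.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import study_config

from sdmshift.pipeline import prepare_stack, simulate_world
from sdmshift.predictors import vif_report_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = study_config()
    world = simulate_world(cfg)
    current, futures, report = prepare_stack(world, cfg)

    df = vif_report_frame(report)
    out = ROOT / "results" / "vif_report.csv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, index=False, float_format="%.6g")

    removed = [r for _, r in report.rounds if r is not None]
    print(f"{len(report.rounds)} VIF round(s); removed: {removed or 'none'}")
    print(f"retained ({len(report.retained)}): {', '.join(report.retained)}")
    final = report.rounds[-1][0]
    if final:
        print("final scores: "
              + ", ".join(f"{k}={v:.2f}" for k, v in final.items()))
    print(f"report written to {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
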