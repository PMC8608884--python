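#!/usr/bin/env python
"""Novel-object preference and ball-pit learning curve.

Scores the simulated contact log (75% programmed novel preference) and the
18 weekly retrieval trials (mean latency programmed to fall linearly from
26.5 s to 7.8 s), then fits the week-by-latency regression the study reports
alongside its learning-curve figure.
"""

from pathlib import Path

import numpy as np

from pigpheno import event_scoring as es
from pigpheno import io_formats as iof
from pigpheno import trends
from pigpheno.synthetic import GroundTruth

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "simulated"


def main() -> None:
    contacts = iof.read_event_table(SIM / "contact_events.csv")
    summary = es.contact_summary(contacts)
    di = es.discrimination_index(summary)
    print(
        f"novel object: {summary.novel_seconds:.0f} s novel vs "
        f"{summary.familiar_seconds:.0f} s familiar "
        f"({summary.novel_pct:.1f}% / {summary.familiar_pct:.1f}%), DI {di:.2f}"
    )

    retrievals = iof.read_event_table(SIM / "retrieval_events.csv")
    truth = GroundTruth.from_yaml(SIM / "retrieval_truth.yaml").truth
    rows = [
        {"session_id": "nor", "metric": "novel_pct", "value": summary.novel_pct, "unit": "%"},
        {"session_id": "nor", "metric": "familiar_pct", "value": summary.familiar_pct, "unit": "%"},
        {"session_id": "nor", "metric": "discrimination_index", "value": di, "unit": "1"},
    ]
    weeks, means = [], []
    for sid, grp in retrievals.data.groupby("session_id", sort=False):
        trial = es.retrieval_trial(iof.EventLog(grp.reset_index(drop=True)))
        weeks.append(float(sid.removeprefix("week")))
        means.append(trial.mean_latency)
        rows.append({"session_id": sid, "metric": "mean_latency", "value": trial.mean_latency, "unit": "s"})
    res = trends.linreg(np.asarray(weeks), np.asarray(means))
    print(
        f"ball pit: week {weeks[0]:.0f} mean {means[0]:.1f} s -> week {weeks[-1]:.0f} "
        f"mean {means[-1]:.1f} s; slope {res.estimates['slope']:.2f} s/week "
        f"(programmed {truth['schedule_slope']:.2f}), R2 {res.r_squared:.2f}, p {res.p:.2g}"
    )
    rows.append({"session_id": "ballpit", "metric": "latency_slope", "value": res.estimates["slope"], "unit": "s/week"})
    with open(ROOT / "object_test_metrics.csv", "w", newline="") as fh:
        iof.write_report(rows, fh)
    print(f"wrote {ROOT / 'object_test_metrics.csv'}")


if __name__ == "__main__":
    main()
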