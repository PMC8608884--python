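#!/usr/bin/env python
"""Generate one study-like synthetic dataset per input stream.

The study's raw recordings are not deposited, so each downstream analysis
runs on a simulated stand-in whose generating parameters mirror the published
magnitudes: a 10-min open-field session, a door-biased session, manually
scored escape bouts, novel/familiar contact bouts with a 75% novel
preference, 18 weekly ball-pit trials with mean latency falling 26.5 -> 7.8 s,
5 days of minute-resolution actigraphy (sleep 23:00-07:45, peak 12:00-16:00),
and a 1.93 m/s gait trial with 30/17/12 degree pod-angle ranges.

Writes the same CSV/TSV dialects the readers accept, each beside a
ground-truth YAML, under results/simulated/.
"""

from pathlib import Path

from pigpheno import io_formats as iof
from pigpheno import synthetic

SEED = 20240304
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    track, gt = synthetic.simulate_openfield(seed=SEED)
    with open(OUT / "openfield_pose.csv", "w", newline="") as fh:
        iof.write_pose_table(track, fh, dialect="three_row")
    gt.to_yaml(OUT / "openfield_truth.yaml")

    biased, gt = synthetic.simulate_openfield(door_bias=0.6, seed=SEED)
    with open(OUT / "openfield_biased_pose.csv", "w", newline="") as fh:
        iof.write_pose_table(biased, fh, dialect="three_row")
    gt.to_yaml(OUT / "openfield_biased_truth.yaml")

    escapes, gt = synthetic.simulate_escapes(seed=SEED)
    with open(OUT / "escape_events.csv", "w", newline="") as fh:
        iof.write_event_table(escapes, fh)
    gt.to_yaml(OUT / "escape_truth.yaml")

    contacts, gt = synthetic.simulate_contacts(p_novel=0.75, n_bouts=200, seed=SEED)
    with open(OUT / "contact_events.csv", "w", newline="") as fh:
        iof.write_event_table(contacts, fh)
    gt.to_yaml(OUT / "contact_truth.yaml")

    retrievals, gt = synthetic.simulate_retrievals(noise_sd=1.0, seed=SEED)
    with open(OUT / "retrieval_events.csv", "w", newline="") as fh:
        iof.write_event_table(retrievals, fh)
    gt.to_yaml(OUT / "retrieval_truth.yaml")

    activity, gt = synthetic.simulate_actigraphy(
        wake_time="07:45", night_bursts=1, seed=SEED
    )
    with open(OUT / "activity.csv", "w", newline="") as fh:
        iof.write_activity_table(activity, fh)
    gt.to_yaml(OUT / "activity_truth.yaml")

    gait, gt = synthetic.simulate_gait(marker_noise_sd=0.001, seed=SEED)
    with open(OUT / "gait_markers.tsv", "w", newline="") as fh:
        iof.write_marker_table(gait, fh)
    gt.to_yaml(OUT / "gait_truth.yaml")

    print(f"wrote 7 datasets + ground truth to {OUT}")


if __name__ == "__main__":
    main()
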