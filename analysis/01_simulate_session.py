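#!/usr/bin/env python
"""Simulate the study's two-height recording session and write it to disk.

One participant performs 400 four-target tapping cycles at each of two
worktable heights.  The HIGH condition is planted with faster
median-frequency decline, higher %MVC activation, larger tap scatter
and slightly faster cycles.  Output: scratch/session/ (raw CSV signals
plus config and ground-truth YAML).
"""
import logging
from pathlib import Path

from tapfatigue.session_io import write_session
from tapfatigue.synthetic import default_config, generate_session

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

OUT = Path(__file__).resolve().parent.parent / "scratch" / "session"
SEED = 7


def main() -> None:
    cfg = default_config(seed=SEED, n_cycles=400)
    dataset = generate_session(cfg)
    write_session(dataset, OUT)
    for height, sess in dataset.sessions.items():
        gt = dataset.ground_truth[height]
        print(f"{height}: {sess.emg.duration:.0f}s EMG at {sess.emg.fs:.0f} Hz, "
              f"{len(sess.taps)} taps, planted MF "
              f"{gt.mf_bins[0, 0]:.1f}->{gt.mf_bins[-1, 0]:.1f} Hz (ANT), "
              f"tap sigma {gt.tap_sigma_mm} mm")
    print(f"session written to {OUT}")


if __name__ == "__main__":
    main()
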