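"""In vitro calcium-imaging analysis on a synthetic video.

Generates a 300-cell, 5-epoch video with known ground truth and runs the
full dF/F0 event pipeline.
"""

import numpy as np

from mendkit.calcium import event_table
from mendkit.synthetic import calcium_preset, gen_calcium_dataset

config = calcium_preset("invitro-0.75", seed=42)
traces, truth = gen_calcium_dataset(config)
print(f"generated {traces.n_cells} cells x {traces.n_frames} frames at "
      f"{traces.fps:g} fps, epochs at {traces.epoch_onsets.tolist()} s")
print(f"planted responsive fraction: {truth.responded.mean():.3f} "
      f"(preset probability {config.p_response})")

table, summary = event_table(traces)
print("\nper-epoch responsiveness:",
      [f"{x:.3f}" for x in summary['responsiveness_per_epoch']])
print(f"spiking probability: {summary['spiking_probability']:.2f}")
print(f"latency: {summary['latency_mean']:.2f} +/- {summary['latency_sd']:.2f} s "
      f"(planted mean {config.latency_mean} s)")
print(f"event rows: {len(table)} responsive (cell, epoch) pairs")

planted = truth.latencies[np.isfinite(truth.latencies)]
print(f"\nplanted latency mean {planted.mean():.2f} s vs recovered "
      f"{summary['latency_mean']:.2f} s -- the detector reads the planted")
print("truth back at frame resolution; the residual gap is noise-driven")
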