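"""Temporal/spatial alignment and per-group error scoring.

Runs one participant's sequences through clap trimming, reference
downsampling, validity masking, scale + rigid alignment, and prints the
per-group mean errors of each method against the reference.
"""

from gesturecap import SimulationConfig, build_cameras, generate_bundle
from gesturecap.align import apply_alignment
from gesturecap.analysis import fit_participant_alignment, prepare_sequence
from gesturecap.metrics import aggregate_participant_means, euclid_errors
import pandas as pd

config = SimulationConfig(n_participants=1, n_sequences=3, duration_s=20.0,
                          margin_s=2.0, seed=2)
cameras, _ = build_cameras(config)
seqs = [
    prepare_sequence(generate_bundle(config, 0, s), cameras)
    for s in range(config.n_sequences)
]
methods = ["stereo_a", "stereo_b", "mono_a", "mono_b"]
params = fit_participant_alignment(seqs, methods)
print("estimated mono scales:",
      {m: round(params[m].transform.s, 3) for m in ("mono_a", "mono_b")})

tables = []
for sd in seqs:
    for m in methods:
        aligned = apply_alignment(sd.methods[m], params[m])
        tables.append(
            euclid_errors(aligned, sd.mocap, sd.mask,
                          participant=sd.participant_id, method=m,
                          sequence=sd.sequence_id)
        )
cells, overall = aggregate_participant_means(pd.concat(tables))
print(cells.pivot_table(index="group", columns="method",
                        values="mean_e_mm", observed=True).round(1))
print(overall.round(1).to_string(index=False))
# Stereo errors sit near the ~10 mm marker-offset floor; monocular errors
# are dominated by the simulated depth degradation.
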