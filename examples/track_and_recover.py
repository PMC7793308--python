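"""Tracking a synthesized motion recovers its muscle activity.

The predicted suspended-mass motion serves as reference data for a
tracking problem (deviation weight 10, squared-excitation weight 0.001).
Because the reference was produced by the same model, the tracking
solution must reproduce the original activations; the printed RMS error
is expressed as a percentage of the peak predicted activation and should
sit far below the 0.47% bound.
"""
from collosim.verify import predict_suspended_mass, tracking_recovery

prediction = predict_suspended_mass(num_mesh_intervals=25,
                                    mesh_schedule=(10,))
report, track = tracking_recovery(prediction, num_mesh_intervals=25)
print(f"tracking status: {track.status} ({track.iterations} iterations)")
print(report)
print("objective terms:", {k: round(v, 6)
                           for k, v in track.objective_terms.items()})
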