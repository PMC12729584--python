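"""Simulate a small OFF/ON cohort and extract the windowed feature matrix.

Three synthetic patients perform the resting-tremor exercise in both
medication states; the tri-axial sensor magnitudes are windowed (1 s, 50%
overlap) and summarised by the 29-feature bank per sensor.
"""

import numpy as np

from gefc.signal_features import extract_feature_matrix
from gefc.simulate import SimulationConfig, generate_cohort

cfg = SimulationConfig(n_patients=3, seed=42)
cohort = generate_cohort(cfg)
sessions = [s for s in cohort.sessions if s.exercise == 0]
matrix = extract_feature_matrix(sessions)

print(f"sessions: {len(sessions)} (3 patients x OFF/ON)")
print(f"feature matrix: {len(matrix)} windows x {len(matrix.column_names)} features")
off, on = matrix.labels == 0, matrix.labels == 1
for col in ("acce_dominant_frequency", "gyro_rmssd", "acce_sample_entropy"):
    print(f"  {col}: OFF mean {matrix.values[col][off].mean():.3f}, "
          f"ON mean {matrix.values[col][on].mean():.3f}")
# The dominant frequency sits in the 4-6 Hz tremor band for both states;
# RMSSD is clearly larger OFF medication (stronger tremor), while sample
# entropy shifts with the balance between oscillation and sensor noise.
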