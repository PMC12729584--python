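"""Cross-validate the FC pipeline against the raw-feature RBF baseline.

A small synthetic cohort, the resting-tremor exercise, stratified 5-fold
CV: feature scoring and construction run inside each training fold only,
and the held-out fold is transformed with the evolved expressions.
"""

from gefc.construction import FCConfig
from gefc.evaluation import EvalConfig, crossval_evaluate
from gefc.signal_features import extract_feature_matrix
from gefc.simulate import SimulationConfig, generate_cohort

cohort = generate_cohort(SimulationConfig(n_patients=6, seed=3))
matrix = extract_feature_matrix([s for s in cohort.sessions if s.exercise == 0])
print(f"dataset: {len(matrix)} windows, {len(matrix.column_names)} features")

ecfg = EvalConfig(folds=5, repeats=1, seed=3)
rbf = crossval_evaluate(matrix, "rbf", ecfg)
fc = crossval_evaluate(
    matrix, "fc", ecfg,
    fc_cfg=FCConfig(generations=25, population=60, n_features=3, seed=3),
)
print(f"raw-feature RBF: error {rbf.mean_error:5.2f}%  "
      f"precision {rbf.mean_precision:.3f}  recall {rbf.mean_recall:.3f}")
print(f"FC (3 features): error {fc.mean_error:5.2f}%  "
      f"precision {fc.mean_precision:.3f}  recall {fc.mean_recall:.3f}")
# The constructed three-feature representation should classify the OFF/ON
# state with a clearly lower error than the same network on all 87 raw
# features, where per-patient amplitude differences swamp the state signal.
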