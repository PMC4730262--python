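"""Full pipeline: profiles -> GapDPC -> SVM-RFE -> RBF-SVM jackknife.

Generates four synthetic structural classes whose signal lives in
gapped-dipeptide propensities, extracts features with G=4, selects the
top 50 by SVM-RFE, and evaluates by leave-one-out with per-class
accuracy and Matthews correlation.
"""

from gapdpc import (
    PipelineConfig,
    SyntheticSpec,
    extract_dataset,
    jackknife,
    make_classed_profiles,
    rank_features,
    select_top_k,
)

spec = SyntheticSpec(n_per_class=15, max_gap=4, class_signal=3.0, seed=1)
profiles, labels, informative = make_classed_profiles(spec)
data = extract_dataset(profiles, labels, max_gap=4)
print(f"extracted {data.n} proteins x {data.n_features} features")

ranking = rank_features(data)
cols = select_top_k(ranking, 50)
print(f"top-50 features contain {len(set(cols.tolist()) & set(informative.tolist()))} "
      f"of the {len(informative)} planted dipeptide pairs")

report = jackknife(data, PipelineConfig(feature_indices=cols))
print()
print(report.to_text())
print()
print("each protein was predicted by a model trained on the other "
      f"{data.n - 1}; per-class MCC near 1 means balanced, confident separation.")
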