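"""Featurize the 30-day sample table and rank variables by PCA.

Each of the nine sensor variables is summarised by eight statistics (mean,
sd, curvature, kurtosis, linearity, Shannon entropy, skewness, trend
strength); PCA on the standardized daily values then ranks the variables
by their contribution to the components that explain 95% of the variance.
"""

import herdmark as hm

table = hm.load_sample_activity_table()
features = hm.build_feature_table(table)
print("feature table (selected columns):")
print(features[["mean", "sd", "shannon_entropy", "trend"]].round(3))

result = hm.fit_pca(table.to_frame()[list(hm.DEFAULT_STATE_SPACE.labels)],
                    threshold=0.95)
print(f"\n{result.n_selected} components explain >= 95% of the variance")
print(hm.rank_variable_contributions(result).round(4).to_string(index=False))
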