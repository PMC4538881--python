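"""A miniature filtering campaign: random column removal vs no filtering.

Simulates 20 families, applies random 25%/60% column removal next to the
mandatory unfiltered control, infers NJ trees and summarises: mean
fraction of wrong splits (with SEM), paired two-sided Wilcoxon p against
the unfiltered control (alpha = 0.01, uncorrected), and the fraction of
families improved/unchanged/worsened.  Random removal can only destroy
signal, so error should rise with the removed fraction.
"""

from filterbench import CampaignConfig, FilterSetting, SimConfig, run_campaign, summarize

config = CampaignConfig(
    n_families=20,
    sim=SimConfig(),
    filters=[FilterSetting("unfiltered", "unfiltered"),
             FilterSetting("random25", "random", {"fraction": 0.25}),
             FilterSetting("random60", "random", {"fraction": 0.60})],
    tree_method="nj",
    seed=7,
)
records = run_campaign(config)
summary = summarize(records)
cols = ["filter", "mean_fraction_removed", "mean_fraction_wrong_splits",
        "sem_fraction_wrong_splits", "wilcoxon_p_vs_unfiltered",
        "significant", "frac_worsened"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
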