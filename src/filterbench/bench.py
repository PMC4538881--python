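"""Campaign orchestration and aggregation statistics.

A campaign simulates (or loads) many gene families, runs every configured
filter on each, infers trees, scores them against the reference topology,
and aggregates per-filter summaries: mean fraction of wrong splits with
standard error, paired two-sided Wilcoxon tests against the mandatory
unfiltered control at alpha = 0.01 (uncorrected, and reported as such),
%-removed vs error curve points, and the fraction of families improved /
unchanged / worsened.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assess import AssessmentRecord, enriched_discordance
from .core import Alignment, Phylotree
from .filters import make_filter
from .inference import nj_tree, pairwise_distances, wls_nni_tree
from .simulate import SimConfig, evolve, make_enriched_problem, write_family

__all__ = [
    "FilterSetting", "CampaignConfig", "run_campaign", "paired_wilcoxon",
    "summarize", "records_to_frame", "ALPHA",
]

#: significance level of the filtered-vs-unfiltered Wilcoxon test
ALPHA = 0.01


@dataclass
class FilterSetting:
    label: str
    name: str
    params: dict = field(default_factory=dict)


@dataclass
class CampaignConfig:
    n_families: int = 100
    sim: SimConfig = field(default_factory=SimConfig)
    filters: Sequence[FilterSetting] = field(default_factory=lambda: [
        FilterSetting("unfiltered", "unfiltered")])
    n_core: Optional[int] = None      # None -> plain test on all taxa
    tree_method: str = "nj"           # "nj" | "wls"
    support: Optional[tuple] = None   # ("bootstrap", n_reps) | ("branch_length", pam)
    support_thresholds: Sequence[float] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [f.label for f in self.filters]
        if "unfiltered" not in labels:
            raise ValueError(
                "campaigns must include the mandatory 'unfiltered' control")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate filter labels")


def _tree_builder(config: CampaignConfig, seed: int):
    from .inference import bootstrap_support, branch_length_support

    def build(aln: Alignment) -> Phylotree:
        def base(a: Alignment) -> Phylotree:
            dm = pairwise_distances(a)
            tree = nj_tree(dm)
            if config.tree_method == "wls":
                tree = wls_nni_tree(dm, start=tree)
            elif config.tree_method != "nj":
                raise ValueError(f"unknown tree method {config.tree_method!r}")
            return tree

        if config.support is None:
            return base(aln)
        kind, value = config.support
        if kind == "bootstrap":
            return bootstrap_support(aln, base, n_reps=int(value), seed=seed)
        if kind == "branch_length":
            return branch_length_support(base(aln), float(value))
        raise ValueError(f"unknown support source {kind!r}")

    return build


def run_campaign(config: CampaignConfig,
                 outdir: Optional[str | Path] = None) -> pd.DataFrame:
    """Run every (family x filter setting) cell of a campaign.

    Families in which *any* filter empties the alignment are excluded from
    the aggregates of all methods (comparability rule), as are families
    where a stage fails.  With ``outdir`` set, per-family artifacts and
    records are written and previously completed families are reused, so
    interrupted campaigns resume idempotently.  More than 50% failed
    families aborts the campaign.
    """
    out = Path(outdir) if outdir is not None else None
    rows: list[dict] = []
    n_failed = 0
    for i in range(config.n_families):
        fam_seed = int(config.seed + i) % (2**31 - 1)
        fam_dir = out / f"fam_{i:04d}" if out is not None else None
        cached = _load_cached(fam_dir)
        if cached is not None:
            rows.extend(cached)
            continue
        try:
            fam_rows = _run_family(config, i, fam_seed, fam_dir)
        except Exception as exc:  # logged, family dropped, campaign continues
            n_failed += 1
            fam_rows = [{"family": f"fam_{i:04d}", "filter": f.label,
                         "excluded": True, "error": repr(exc)}
                        for f in config.filters]
        rows.extend(fam_rows)
        if fam_dir is not None:
            fam_dir.mkdir(parents=True, exist_ok=True)
            (fam_dir / "records.json").write_text(json.dumps(fam_rows))
    if n_failed > config.n_families / 2:
        raise RuntimeError(
            f"{n_failed}/{config.n_families} families failed; aborting")
    df = records_to_frame(rows)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "records.tsv", sep="\t", index=False)
    return df


def _load_cached(fam_dir: Optional[Path]):
    if fam_dir is None or not (fam_dir / "records.json").exists():
        return None
    return json.loads((fam_dir / "records.json").read_text())


def _run_family(config: CampaignConfig, index: int, fam_seed: int,
                fam_dir: Optional[Path]) -> list[dict]:
    sim = SimConfig(**{**asdict(config.sim), "seed": fam_seed})
    family = evolve(sim)
    if config.n_core is None or config.n_core >= sim.n_taxa:
        core = set(family.true_tree.leaf_names())
        reference = family.true_tree
    else:
        core, reference = make_enriched_problem(
            family, n_core=config.n_core, seed=fam_seed + 1)
    if fam_dir is not None:
        write_family(family, fam_dir)
        reference.write(fam_dir / "reference.nwk")
    builder = _tree_builder(config, seed=fam_seed + 2)
    fam_rows = []
    for k, setting in enumerate(config.filters):
        filter_fn = make_filter(setting.name, setting.params,
                                seed=fam_seed + 1000 + k)
        rec = enriched_discordance(
            family, core, reference, filter_fn, builder,
            aligner=None, support_thresholds=config.support_thresholds,
            filter_name=setting.label)
        row = _record_to_row(rec, f"fam_{index:04d}", setting.label)
        fam_rows.append(row)
    return fam_rows


def _record_to_row(rec: AssessmentRecord, family: str, label: str) -> dict:
    row = {
        "family": family,
        "filter": label,
        "fraction_removed": rec.fraction_removed,
        "fraction_wrong_splits": rec.fraction_wrong_splits,
        "precision": rec.precision,
        "recall": rec.recall,
        "excluded": rec.excluded,
        "error": rec.error,
    }
    for th, (tp, fp, fn) in rec.support_counts.items():
        row[f"tp_{th}"] = tp
        row[f"fp_{th}"] = fp
        row[f"fn_{th}"] = fn
    return row


def records_to_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if "excluded" in df:
        df["excluded"] = df["excluded"].fillna(False).astype(bool)
    return df


# ---------------------------------------------------------------------------
# Statistics


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-family metrics.

    Zero differences are dropped (standard convention); if every difference
    is zero the test carries no evidence and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) == 0:
        raise ValueError("empty samples")
    diffs = x - y
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, zero_method="wilcox",
                                alternative="two-sided").pvalue)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-filter summary against the unfiltered control.

    Excluded families are dropped from *every* method before aggregation
    (strict intersection), so all rows are paired by family.  The Wilcoxon
    test is two-sided at alpha = 0.01 with no multiple-testing correction
    (reported as-is; interpret stars accordingly).
    """
    if "unfiltered" not in set(records["filter"]):
        raise ValueError("records lack the 'unfiltered' control")
    bad_families = set(records.loc[records["excluded"], "family"])
    kept = records[~records["family"].isin(bad_families)].copy()
    if kept.empty:
        raise ValueError("all families excluded")
    control = (kept[kept["filter"] == "unfiltered"]
               .set_index("family")["fraction_wrong_splits"])
    out = []
    for label, grp in kept.groupby("filter", sort=False):
        grp = grp.set_index("family").loc[control.index]
        err = grp["fraction_wrong_splits"]
        n = len(err)
        p = paired_wilcoxon(err.to_numpy(), control.to_numpy())
        diffs = err.to_numpy() - control.to_numpy()
        out.append({
            "filter": label,
            "n_families": n,
            "mean_fraction_removed": float(grp["fraction_removed"].mean()),
            "mean_fraction_wrong_splits": float(err.mean()),
            "sem_fraction_wrong_splits": (
                float(err.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan),
            "mean_precision": float(grp["precision"].mean())
                if "precision" in grp and grp["precision"].notna().any() else np.nan,
            "mean_recall": float(grp["recall"].mean())
                if "recall" in grp and grp["recall"].notna().any() else np.nan,
            "wilcoxon_p_vs_unfiltered": p,
            "significant": bool(p < ALPHA) and label != "unfiltered",
            "frac_improved": float((diffs < 0).mean()),
            "frac_unchanged": float((diffs == 0).mean()),
            "frac_worsened": float((diffs > 0).mean()),
        })
    return pd.DataFrame(out)


def removal_error_curve(summary: pd.DataFrame,
                        labels: Sequence[str]) -> pd.DataFrame:
    """%-sites-removed vs mean error curve points for a family of filter
    settings (linear interpolation between grid points is the intended
    rendering)."""
    rows = summary[summary["filter"].isin(labels)]
    rows = rows.sort_values("mean_fraction_removed")
    return rows[["filter", "mean_fraction_removed",
                 "mean_fraction_wrong_splits",
                 "sem_fraction_wrong_splits"]].reset_index(drop=True)
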