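"""Data-retention rules producing the analysis-ready subset.

Rows are kept when they carry at least ``min_total_count`` reads and come
from a sample whose contamination, where measurable, is strictly below
``max_contamination``.  For parent-of-origin testing the subset is further
restricted to phased heterozygous rows.  Dropped rows are attributed to the
first failing rule in a fixed order (count, contamination, phasing) so the
accounting is deterministic, and retained + dropped always equals input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RULE_ORDER = ("min_total_count", "contamination", "unphased")


@dataclass
class FilterConfig:
    min_total_count: int = 10
    max_contamination: float = 0.05
    drop_unmeasurable_contamination: bool = False
    require_phased: bool = False

    def __post_init__(self) -> None:
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")
        if not 0.0 <= self.max_contamination <= 1.0:
            raise ValueError("max_contamination must lie in [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    drops: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": "input", "rows": self.n_input}]
        rows += [{"rule": f"dropped_{r}", "rows": self.drops.get(r, 0)} for r in RULE_ORDER]
        rows.append({"rule": "retained", "rows": self.n_retained})
        return pd.DataFrame(rows)


def apply_filters(
    sites: pd.DataFrame,
    contam: pd.DataFrame | None,
    cfg: FilterConfig,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply retention rules; return the retained table and drop accounting.

    ``contam`` is the per-sample contamination table (est_homalt / est_ref
    columns); a sample whose estimates are all undefined passes the
    contamination rule unless ``drop_unmeasurable_contamination`` is set.
    """
    n_input = len(sites)
    if n_input == 0:
        return sites.copy(), FilterReport(0, 0, {r: 0 for r in RULE_ORDER})

    fail_count = sites["total_count"] < cfg.min_total_count

    if contam is not None and len(contam):
        per_sample = contam.set_index("sample_id")[["est_homalt", "est_ref"]].max(
            axis=1, skipna=True
        )
        est = sites["sample_id"].map(per_sample)
    else:
        est = pd.Series(np.nan, index=sites.index)
    measurable = est.notna()
    fail_contam = (measurable & (est >= cfg.max_contamination)) | (
        ~measurable & cfg.drop_unmeasurable_contamination
    )

    if cfg.require_phased:
        if "paternal_allele" in sites.columns:
            fail_phase = sites["paternal_allele"] == "unknown"
        else:
            fail_phase = ~sites.get("phased", pd.Series(False, index=sites.index)).astype(bool)
    else:
        fail_phase = pd.Series(False, index=sites.index)

    # attribute each dropped row to its first failing rule
    first_fail = np.select(
        [fail_count, fail_contam, fail_phase],
        ["min_total_count", "contamination", "unphased"],
        default="",
    )
    drops = {rule: int((first_fail == rule).sum()) for rule in RULE_ORDER}
    retained = sites.loc[first_fail == ""].reset_index(drop=True)
    report = FilterReport(n_input=n_input, n_retained=len(retained), drops=drops)
    assert report.n_retained + sum(drops.values()) == n_input
    return retained, report
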