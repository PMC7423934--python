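"""Descriptive cohort statistics and one-way ANOVA.

Group summaries are reported as mean +/- population standard deviation
(divisor n); published clinical tables for small surgical cohorts are
commonly summarized with the population form, and the bundled reference
cohort reproduces its printed SDs only under divisor n.  The sample SD
(divisor n-1) is available via ``ddof=1``.

The module bundles the clinical table of the 14-patient early lung
adenocarcinoma cohort (5 AIS, 5 MIA, 4 LPA) that the synthetic generator's
group design emulates, so that descriptive statistics have a concrete
worked example.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GroupDesign, LepinetError

#: clinical table of the reference early-lung-adenocarcinoma cohort:
#: subtype, age (years), sex, tumour size on CT (mm)
_COHORT_TSV = """\
sample_id\tgroup\tage\tsex\ttumour_size_mm
AIS_T53\tAIS\t53\tF\t11
AIS_T54\tAIS\t74\tM\t29
AIS_T56\tAIS\t69\tF\t16
AIS_T58\tAIS\t78\tM\t28
AIS_T59\tAIS\t68\tF\t13
MIA_T73\tMIA\t58\tM\t20
MIA_T74\tMIA\t67\tF\t19
MIA_T75\tMIA\t77\tF\t20
MIA_T79\tMIA\t61\tM\t10
MIA_T80\tMIA\t63\tF\t12
LPA_T85\tLPA\t68\tM\t30
LPA_T87\tLPA\t73\tF\t28
LPA_T88\tLPA\t59\tM\t30
LPA_T89\tLPA\t67\tF\t20
"""


def reference_cohort() -> pd.DataFrame:
    """Clinical table of the bundled 14-patient AIS/MIA/LPA cohort."""
    return pd.read_csv(io.StringIO(_COHORT_TSV), sep="\t")


def reference_design() -> GroupDesign:
    df = reference_cohort()
    return GroupDesign(pd.Series(df["group"].values, index=df["sample_id"], name="group"))


@dataclass
class GroupDescriptives:
    """Per-group n/mean/SD plus the one-way ANOVA F and p."""

    table: pd.DataFrame  # columns: group, n, mean, sd
    anova_f: float
    anova_p: float


def describe_groups(values: pd.Series, design: GroupDesign, ddof: int = 0) -> pd.DataFrame:
    """Per-group n, mean and SD (population SD by default)."""
    missing = [s for s in design.sample_ids if s not in values.index or pd.isna(values[s])]
    if missing:
        raise LepinetError(f"missing values for samples: {missing}")
    rows = []
    for g in design.group_labels:
        v = values.loc[design.samples_of(g)].to_numpy(dtype=float)
        rows.append({"group": g, "n": len(v), "mean": float(np.mean(v)),
                     "sd": float(np.std(v, ddof=ddof))})
    return pd.DataFrame(rows)


def one_way_anova(values: pd.Series, design: GroupDesign) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA across the design's groups."""
    labels = design.group_labels
    if len(labels) < 2:
        raise LepinetError("ANOVA needs at least 2 groups")
    groups = [values.loc[design.samples_of(g)].to_numpy(dtype=float) for g in labels]
    n_total = sum(len(g) for g in groups)
    if n_total <= len(groups):
        raise LepinetError("ANOVA needs total n > number of groups")
    if all(np.std(g) == 0 for g in groups):
        means = [np.mean(g) for g in groups]
        if np.ptp(means) > 0:
            return float("inf"), 0.0  # zero within-group variance, unequal means
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def cohort_descriptives(values: pd.Series, design: GroupDesign, ddof: int = 0) -> GroupDescriptives:
    table = describe_groups(values, design, ddof=ddof)
    f, p = one_way_anova(values, design)
    return GroupDescriptives(table, f, p)
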