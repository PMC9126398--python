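"""Multi-reader agreement statistics.

The unit of analysis is a tidy measurement table with one row per
(lesion_id, reader_id, session) and columns ``adc_value`` (1e-6 mm^2/s)
plus session-specific ROI geometry.  Sessions code the three measurement
methods:

1. free 2D small-ROI (reader's habitual size and placement),
2. 9-pixel 2D small-ROI covering the lowest-ADC area,
3. 10th percentile of a 3D whole-lesion ROI.

Provided statistics:

* multi-reader Bland-Altman limits of agreement, with differences taken
  from the per-lesion mean across readers (bias +- 1.96 x SD);
* ICC of each reader against the computer-calculated reference (two-way
  random, absolute agreement, single measures by default);
* Friedman omnibus across the three methods on absolute deviations, with
  Wilcoxon post-hoc tests Holm-adjusted;
* unpaired t-tests for technical group contrasts (scanner model, coil).

:class:`AgreementStudy` bundles these into a fit/results object with a
summary table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

SESSIONS = (1, 2, 3)

MEASUREMENT_COLUMNS = ("lesion_id", "reader_id", "session", "adc_value")


def check_complete_block(table: pd.DataFrame, session: int) -> pd.DataFrame:
    """Rows of one session, validated as a complete lesion x reader block.

    Raises ``ValueError`` naming the missing (lesion, reader) cells when the
    block design is incomplete, or the duplicated cells when over-complete.
    """
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"measurement table lacks columns {missing_cols}")
    sub = table[table["session"] == session]
    if sub.empty:
        raise ValueError(f"no rows for session {session}")
    lesions = sorted(sub["lesion_id"].unique())
    readers = sorted(sub["reader_id"].unique())
    cells = set(zip(sub["lesion_id"], sub["reader_id"]))
    expected = set(itertools.product(lesions, readers))
    missing = sorted(expected - cells)
    if missing:
        raise ValueError(
            f"incomplete block for session {session}: missing "
            f"(lesion, reader) cells {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    if len(sub) != len(expected):
        dup = sub[sub.duplicated(["lesion_id", "reader_id"], keep=False)]
        raise ValueError(
            f"duplicated (lesion, reader) cells in session {session}: "
            f"{sorted(set(zip(dup['lesion_id'], dup['reader_id'])))[:10]}"
        )
    if not np.all(np.isfinite(sub["adc_value"])) or np.any(sub["adc_value"] <= 0):
        raise ValueError(f"session {session} has non-finite or non-positive ADC values")
    return sub


@dataclass(frozen=True)
class AgreementResult:
    """Multi-reader Bland-Altman summary for one session.

    ``loa_half_width`` is the half-width of the 95% limits of agreement,
    1.96 x SD of all reader-minus-lesion-mean differences.  ``deviations``
    is the long table of those differences (lesion_id, reader_id, diff) for
    downstream Friedman analysis.
    """

    session: int
    bias: float
    sd_diff: float
    loa_half_width: float
    n_lesions: int
    n_readers: int
    deviations: pd.DataFrame = field(repr=False)


def bland_altman_multireader(
    table: pd.DataFrame, session: int, ddof: int = 1
) -> AgreementResult:
    """Bland-Altman limits of agreement among readers for one session.

    For each lesion the per-lesion mean across readers is the comparator;
    each reader's difference from that mean enters a pooled SD whose
    1.96-multiple is the LoA half-width.  ``ddof`` selects the SD
    denominator convention (1 = sample SD, the default).
    """
    sub = check_complete_block(table, session)
    n_readers = sub["reader_id"].nunique()
    n_lesions = sub["lesion_id"].nunique()
    if n_readers < 2 or n_lesions < 2:
        raise ValueError("need >= 2 readers and >= 2 lesions")
    lesion_mean = sub.groupby("lesion_id")["adc_value"].transform("mean")
    diffs = sub["adc_value"] - lesion_mean
    sd = float(np.std(diffs, ddof=ddof))
    dev = sub[["lesion_id", "reader_id"]].copy()
    dev["diff"] = diffs.to_numpy()
    dev["lesion_mean"] = lesion_mean.to_numpy()
    return AgreementResult(
        session=session,
        bias=float(diffs.mean()),
        sd_diff=sd,
        loa_half_width=1.96 * sd,
        n_lesions=n_lesions,
        n_readers=n_readers,
        deviations=dev.reset_index(drop=True),
    )


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation of one reader against the reference."""

    estimate: float
    ci_low: float
    ci_high: float
    model_tag: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.estimate <= 1.0 + 1e-12:
            raise ValueError(f"ICC estimate out of range: {self.estimate}")


def icc_vs_reference(
    reader_values: np.ndarray | list[float],
    reference_values: np.ndarray | list[float],
    model: str = "ICC2",
) -> ICCResult:
    """ICC between one reader's per-lesion values and the reference.

    The reader and the computed reference are treated as two raters scoring
    the same lesions.  ``model`` selects the form: ``"ICC2"`` (two-way
    random effects, absolute agreement, single measures — the default,
    sensitive to fixed bias) or ``"ICC3"`` (two-way mixed, consistency).
    The 95% CI is the standard F-based interval.
    """
    x = np.asarray(reader_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("reader and reference must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError(f"need >= 3 lesions for ICC, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in ICC input")
    if model not in ("ICC2", "ICC3"):
        raise ValueError(f"unknown ICC model {model!r}")
    stacked = np.concatenate([x, y])
    if np.ptp(stacked) == 0:
        raise ValueError("zero total variance: ICC undefined")
    if np.array_equal(x, y):
        # Degenerate perfect agreement: residual variance is exactly zero.
        return ICCResult(estimate=1.0, ci_low=1.0, ci_high=1.0, model_tag=model)
    n = len(x)
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["reader", "reference"], n),
            "score": stacked,
        }
    )
    with warnings.catch_warnings():
        # exact affine agreement gives a zero residual mean square, which
        # makes pingouin warn while computing forms we do not report
        warnings.simplefilter("ignore", RuntimeWarning)
        icc = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
    # McGraw-Wong labels: A = absolute agreement (two-way random, ICC2),
    # C = consistency (two-way mixed, ICC3); single measures.
    row = icc.loc[{"ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}[model]]
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    return ICCResult(
        estimate=float(row["ICC"]),
        ci_low=ci_low,
        ci_high=ci_high,
        model_tag={
            "ICC2": "two-way random, absolute agreement, single measures",
            "ICC3": "two-way mixed, consistency, single measures",
        }[model],
    )


def _deviation_blocks(deviation_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (block_id, session, abs_dev) table to blocks x sessions."""
    required = {"block_id", "session", "abs_dev"}
    if not required.issubset(deviation_table.columns):
        raise ValueError(f"deviation table needs columns {sorted(required)}")
    wide = deviation_table.pivot(index="block_id", columns="session", values="abs_dev")
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete blocks (missing sessions) for {bad[:10]}")
    return wide


def friedman_across_methods(deviation_table: pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square across measurement methods.

    ``deviation_table`` is long with columns (block_id, session, abs_dev);
    blocks are lesion x reader cells (or lesions, per caller's choice of
    block_id).  Mid-ranks handle ties.  Returns (statistic, p).
    """
    wide = _deviation_blocks(deviation_table)
    if wide.shape[1] < 3:
        raise ValueError("Friedman test needs >= 3 methods")
    cols = [wide[c].to_numpy() for c in wide.columns]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        return 0.0, 1.0  # all ranks tied; scipy rejects the degenerate case
    stat, p = stats.friedmanchisquare(*cols)
    return float(stat), float(p)


def posthoc_pairwise(
    deviation_table: pd.DataFrame,
    pairs: list[tuple[int, int]] | None = None,
    flavor: str = "ranksums",
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests between methods, Holm-adjusted.

    ``flavor`` is ``"ranksums"`` (two-sample rank sum, as reported) or
    ``"signed_rank"`` (paired signed-rank, the design-consistent variant).
    Returns a DataFrame with columns (method_a, method_b, p_raw, p_holm).
    """
    if flavor not in ("ranksums", "signed_rank"):
        raise ValueError(f"unknown post-hoc flavor {flavor!r}")
    wide = _deviation_blocks(deviation_table)
    methods = list(wide.columns)
    if len(methods) < 2:
        raise ValueError("post-hoc tests need >= 2 methods")
    if pairs is None:
        pairs = list(itertools.combinations(methods, 2))
    raws = []
    for a, b in pairs:
        xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
        if np.array_equal(xa, xb):
            raws.append(1.0)
        elif flavor == "ranksums":
            raws.append(float(stats.ranksums(xa, xb).pvalue))
        else:
            raws.append(float(stats.wilcoxon(xa, xb).pvalue))
    _, p_holm, _, _ = multipletests(raws, method="holm")
    return pd.DataFrame(
        {
            "method_a": [a for a, _ in pairs],
            "method_b": [b for _, b in pairs],
            "p_raw": raws,
            "p_holm": p_holm,
        }
    )


def holm_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    _, adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="holm")
    return adj


def unpaired_group_test(
    values_a: np.ndarray | list[float],
    values_b: np.ndarray | list[float],
    equal_var: bool = False,
) -> tuple[float, float, float, float]:
    """Two-sample t-test between independent groups.

    Welch by default (``equal_var=False``); Student with ``equal_var=True``.
    Returns (t, p, mean_a, mean_b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0, float(a.mean()), float(b.mean())
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), float(a.mean()), float(b.mean())


# ---------------------------------------------------------------------------
# High-level fit/results surface


class AgreementStudy:
    """Full multi-reader agreement analysis of a measurement table.

    Parameters
    ----------
    measurements : DataFrame
        Tidy table with (lesion_id, reader_id, session, adc_value) and
        optional roi_size_mm2 / roi_volume_cm3 columns.
    reference : DataFrame, optional
        Per-lesion computer reference values with columns
        (lesion_id, ref_9px, ref_p10); enables the per-reader ICC block.
    icc_model : str
        "ICC2" (absolute agreement, default) or "ICC3" (consistency).
    friedman_block : str
        "cell" — blocks are lesion x reader absolute deviations from the
        reference (default); "lesion" — per-lesion mean absolute deviation.
    """

    def __init__(
        self,
        measurements: pd.DataFrame,
        reference: pd.DataFrame | None = None,
        icc_model: str = "ICC2",
        friedman_block: str = "cell",
        posthoc_flavor: str = "ranksums",
        ddof: int = 1,
    ) -> None:
        if friedman_block not in ("cell", "lesion"):
            raise ValueError(f"unknown friedman_block {friedman_block!r}")
        self.measurements = measurements
        self.reference = reference
        self.icc_model = icc_model
        self.friedman_block = friedman_block
        self.posthoc_flavor = posthoc_flavor
        self.ddof = ddof

    def _deviation_table(self) -> pd.DataFrame:
        """Absolute deviations from the per-lesion reader mean, long form."""
        rows = []
        for session in SESSIONS:
            res = bland_altman_multireader(self.measurements, session, ddof=self.ddof)
            d = res.deviations.copy()
            d["session"] = session
            d["abs_dev"] = d["diff"].abs()
            rows.append(d)
        long = pd.concat(rows, ignore_index=True)
        if self.friedman_block == "cell":
            long["block_id"] = (
                long["lesion_id"].astype(str) + "|" + long["reader_id"].astype(str)
            )
            return long[["block_id", "session", "abs_dev"]]
        agg = (
            long.groupby(["lesion_id", "session"])["abs_dev"].mean().reset_index()
        )
        return agg.rename(columns={"lesion_id": "block_id"})

    def fit(self) -> "AgreementResults":
        loa = {
            s: bland_altman_multireader(self.measurements, s, ddof=self.ddof)
            for s in SESSIONS
        }
        dev = self._deviation_table()
        friedman_stat, friedman_p = friedman_across_methods(dev)
        posthoc = posthoc_pairwise(dev, flavor=self.posthoc_flavor)
        icc = None
        if self.reference is not None:
            icc = self._icc_table()
        return AgreementResults(
            loa=loa,
            friedman_stat=friedman_stat,
            friedman_p=friedman_p,
            posthoc=posthoc,
            icc=icc,
            icc_model=self.icc_model,
        )

    def _icc_table(self) -> pd.DataFrame:
        ref = self.reference.set_index("lesion_id")
        ref_col = {1: "ref_9px", 2: "ref_9px", 3: "ref_p10"}
        records = []
        for session in SESSIONS:
            sub = check_complete_block(self.measurements, session)
            for reader, grp in sub.groupby("reader_id"):
                grp = grp.set_index("lesion_id").sort_index()
                r = ref.loc[grp.index, ref_col[session]].to_numpy()
                icc = icc_vs_reference(
                    grp["adc_value"].to_numpy(), r, model=self.icc_model
                )
                records.append(
                    {
                        "session": session,
                        "reader_id": reader,
                        "icc": icc.estimate,
                        "ci_low": icc.ci_low,
                        "ci_high": icc.ci_high,
                        "mean_diff": float((grp["adc_value"].to_numpy() - r).mean()),
                    }
                )
        return pd.DataFrame(records)


@dataclass
class AgreementResults:
    """Fitted agreement analysis: LoA per session, omnibus and post-hoc
    method comparison, and per-reader ICC against the reference."""

    loa: dict[int, AgreementResult]
    friedman_stat: float
    friedman_p: float
    posthoc: pd.DataFrame
    icc: pd.DataFrame | None
    icc_model: str

    def loa_half_widths(self) -> dict[int, float]:
        return {s: r.loa_half_width for s, r in self.loa.items()}

    def icc_range(self, session: int) -> tuple[float, float]:
        if self.icc is None:
            raise ValueError("no reference table was supplied; ICC unavailable")
        sub = self.icc[self.icc["session"] == session]["icc"]
        return float(sub.min()), float(sub.max())

    def summary(self) -> str:
        lines = ["Multi-reader ADC agreement", "=" * 42]
        for s, r in sorted(self.loa.items()):
            lines.append(
                f"session {s}: LoA +-{r.loa_half_width:7.1f}  "
                f"(SD {r.sd_diff:6.1f}, {r.n_lesions} lesions x {r.n_readers} readers)"
            )
        lines.append(
            f"Friedman across methods: chi2 = {self.friedman_stat:.2f}, "
            f"p = {self.friedman_p:.2e}"
        )
        for row in self.posthoc.itertuples():
            lines.append(
                f"  session {row.method_a} vs {row.method_b}: "
                f"p_holm = {row.p_holm:.3g}"
            )
        if self.icc is not None:
            lines.append(f"ICC vs reference ({self.icc_model}):")
            for s in sorted(self.icc["session"].unique()):
                lo, hi = self.icc_range(s)
                lines.append(f"  session {s}: range {lo:.3f} - {hi:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "loa": {
                str(s): {
                    "bias": r.bias,
                    "sd_diff": r.sd_diff,
                    "loa_half_width": r.loa_half_width,
                    "n_lesions": r.n_lesions,
                    "n_readers": r.n_readers,
                }
                for s, r in self.loa.items()
            },
            "friedman": {"statistic": self.friedman_stat, "p": self.friedman_p},
            "posthoc": self.posthoc.to_dict(orient="records"),
        }
        if self.icc is not None:
            out["icc"] = self.icc.to_dict(orient="records")
            out["icc_model"] = self.icc_model
        return out
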