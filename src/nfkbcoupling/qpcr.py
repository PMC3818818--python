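"""qPCR expression analysis: comparative-Ct quantitation, Z-scores,
standard curves and ChIP fold enrichment.

Relative expression follows the comparative-Ct (ΔΔCt) method against a
reference gene (human polymerase beta by default) and a control sample,
assuming 100% amplification efficiency (one Ct cycle = a factor of two).
Row-wise Z-scores use the sample (n-1) standard deviation. Genomic-DNA
standard curves are ordinary least-squares fits of Ct against log10 mass,
from which amplification efficiency is ``10^(-1/slope) - 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("nfkbcoupling")

CT_COLUMNS = ["gene", "pathway", "condition", "time_min", "replicate", "ct"]

#: Default reference assay (housekeeping gene) for ΔΔCt.
DEFAULT_REFERENCE_GENE = "POLB"


class CtTable:
    """Long-format threshold-cycle table.

    One record per (gene, condition, time, replicate); ``ct`` may be NaN
    for unmeasured reactions. Ct values must lie in (0, 40] when present.
    """

    def __init__(self, records: pd.DataFrame) -> None:
        missing = set(CT_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"CtTable missing columns {sorted(missing)}")
        df = records[CT_COLUMNS].copy()
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        bad = df["ct"].notna() & ((df["ct"] <= 0) | (df["ct"] > 40))
        if bad.any():
            raise ValueError(
                f"Ct values outside (0, 40]: {df.loc[bad].head().to_dict('records')}"
            )
        key = ["gene", "condition", "time_min", "replicate"]
        if df.duplicated(key).any():
            dup = df[df.duplicated(key, keep=False)].head()
            raise ValueError(f"duplicate (gene, condition, time, replicate): {dup}")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path) -> "CtTable":
        return cls(pd.read_csv(path, na_values=["NA"]))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, na_rep="NA")

    def mean_ct(self) -> pd.DataFrame:
        """Replicates averaged on the Ct scale per (gene, condition, time)."""
        return (
            self.records.groupby(["gene", "condition", "time_min"], sort=True)["ct"]
            .mean()
            .reset_index()
        )


class ExpressionMatrix:
    """Genes × (condition, time) values with explicit missing entries."""

    VALUE_KINDS = ("fold_change", "zscore")

    def __init__(self, data: pd.DataFrame, value_kind: str) -> None:
        if value_kind not in self.VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {self.VALUE_KINDS}")
        if not isinstance(data.columns, pd.MultiIndex):
            raise ValueError("columns must be a (condition, time_min) MultiIndex")
        self.data = data.astype(float)
        self.value_kind = value_kind

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = [f"{c}:{t:g}" for c, t in out.columns]
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, value_kind: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene", na_values=["NA"])
        cols = []
        for c in df.columns:
            cond, t = c.rsplit(":", 1)
            cols.append((cond, float(t)))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "time_min"])
        return cls(df, value_kind)


def ddct_fold_change(
    ct: CtTable,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_condition: str = "control",
    control_time_min: float | None = None,
) -> ExpressionMatrix:
    """Relative expression as 2^-ΔΔCt against reference gene and control.

    ΔCt = Ct_gene - Ct_reference per (condition, time) after averaging
    replicates on the Ct scale; ΔΔCt subtracts each gene's ΔCt in the
    control column (``control_condition`` at ``control_time_min``, the
    earliest time by default), so the control column equals 1 by
    construction. Columns whose reference Ct is missing are emitted as
    missing with a logged warning; missing inputs propagate.
    """
    mean = ct.mean_ct()
    wide = mean.pivot(index="gene", columns=["condition", "time_min"], values="ct")
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref = wide.loc[reference_gene]
    genes = wide.drop(index=reference_gene)
    bad_cols = ref[ref.isna()].index
    if len(bad_cols):
        logger.warning(
            "WARN ddct reference Ct missing for columns %s; emitted as NA",
            list(bad_cols),
        )
    dct = genes.sub(ref, axis=1)
    dct[bad_cols] = np.nan
    conds = dct.columns.get_level_values("condition")
    if control_condition not in set(conds):
        raise ValueError(f"control condition {control_condition!r} absent")
    ctrl_times = dct.columns[conds == control_condition].get_level_values("time_min")
    t0 = float(min(ctrl_times)) if control_time_min is None else control_time_min
    if (control_condition, t0) not in dct.columns:
        raise ValueError(f"no control column ({control_condition!r}, {t0})")
    ddct = dct.sub(dct[(control_condition, t0)], axis=0)
    fold = 2.0 ** (-ddct)
    fold = fold.sort_index(axis=1)
    return ExpressionMatrix(fold, "fold_change")


def zscore_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise standardisation of fold changes over observed entries.

    Each row is centred on its mean and scaled by its sample (n-1)
    standard deviation; missing cells are preserved, constant rows map to
    all zeros, and rows with fewer than two observed entries become all
    missing.
    """
    if m.value_kind != "fold_change":
        raise ValueError("zscore_transform expects a fold-change matrix")
    if m.data.empty:
        raise ValueError("empty expression matrix")
    out = m.data.copy()
    for gene, row in m.data.iterrows():
        obs = row.dropna()
        if len(obs) < 2:
            out.loc[gene] = np.nan
            continue
        sd = obs.std(ddof=1)
        if sd == 0:
            out.loc[gene] = np.where(row.notna(), 0.0, np.nan)
        else:
            out.loc[gene] = (row - obs.mean()) / sd
    return ExpressionMatrix(out, "zscore")


# ---------------------------------------------------------------------------
# primer panel
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["pathway", "gene", "accession", "amplicon_bp",
                 "fwd_primer", "rev_primer"]


def load_panel(path=None) -> pd.DataFrame:
    """Load a primer-panel definition (tab-separated).

    Defaults to the shipped 50-assay panel covering canonical NF-κB,
    noncanonical/EMT, interferon, growth-factor, ROS/DNA-damage and
    cell-cycle genes. Primers are validated to contain only A/C/G/T and
    amplicon lengths to lie within 50-160 bp.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "primer_panel.tsv"
    panel = pd.read_csv(path, sep="\t")
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns {sorted(missing)}")
    for col in ("fwd_primer", "rev_primer"):
        bad = ~panel[col].str.fullmatch("[ACGT]+")
        if bad.any():
            raise ValueError(f"non-ACGT characters in {col}: "
                             f"{panel.loc[bad, 'gene'].tolist()}")
    if not panel["amplicon_bp"].between(50, 160).all():
        raise ValueError("amplicon lengths must lie within [50, 160] bp")
    return panel


# ---------------------------------------------------------------------------
# genomic-DNA standard curves and ChIP quantitation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct = slope * log10(mass_ng) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct_from_mass(self, mass_ng: float) -> float:
        return self.slope * math.log10(mass_ng) + self.intercept

    def mass_from_ct(self, ct: float) -> float:
        """Invert the curve: absolute template mass in ng."""
        return 10.0 ** ((ct - self.intercept) / self.slope)


def fit_standard_curve(dilutions) -> StandardCurve:
    """Fit a dilution series of (mass_ng, Ct) pairs.

    Requires at least three points spanning at least one decade of mass;
    a valid curve has negative slope (less template -> later Ct).
    """
    pts = [(float(m), float(c)) for m, c in dilutions]
    if len(pts) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    masses = np.array([m for m, _ in pts])
    cts = np.array([c for _, c in pts])
    if np.any(masses <= 0):
        raise ValueError("masses must be > 0 ng")
    logm = np.log10(masses)
    if logm.max() - logm.min() < 1.0:
        raise ValueError("dilution series must span >= 1 log10 unit of mass")
    fit = stats.linregress(logm, cts)
    return StandardCurve(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue**2))


def chip_fold_enrichment(ip_quantity_ng: float, input_quantity_ng: float,
                         baseline_ratio: float) -> float:
    """ChIP enrichment: IP/input normalised to the unstimulated ratio."""
    if input_quantity_ng <= 0:
        raise ValueError("input quantity must be > 0")
    if baseline_ratio <= 0:
        raise ValueError("baseline ratio must be > 0")
    return (ip_quantity_ng / input_quantity_ng) / baseline_ratio
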