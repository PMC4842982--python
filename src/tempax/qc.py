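"""Spike-in calibrated detection thresholding and sample quality control.

The detection threshold is the median signal of the 20-copy spike-in probe
across cells; probes whose maximum signal reaches that threshold are kept
("over-20-copies" filter). Sample QC checks spike linearity (log signal vs
log copies for spikes at >= 20 copies) and housekeeping gene detection.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, QpcrTable

DEFAULT_SPIKE20 = "AFFX-r2-Bs-phe-3_at"
DEFAULT_HOUSEKEEPING = ("Gapdh", "Actb", "Aldoa", "Pabpn1")


@dataclasses.dataclass
class QcReport:
    """Result bundle of a QC run, serializable to JSON."""

    copy_threshold: float
    spike_fits: pd.DataFrame  # per cell: slope, r2, flagged
    sample_pass: dict[str, bool]
    reasons: dict[str, list[str]]
    retained_probes: list[str]

    def __post_init__(self) -> None:
        if self.copy_threshold <= 0:
            raise ValueError("copy_threshold must be positive")
        for cell, ok in self.sample_pass.items():
            if not ok and not self.reasons.get(cell):
                raise ValueError(f"failed sample {cell} has no reason")

    def to_dict(self) -> dict:
        return {
            "copy_threshold": self.copy_threshold,
            "spike_fits": self.spike_fits.round(6).to_dict(orient="index"),
            "sample_pass": self.sample_pass,
            "reasons": self.reasons,
            "retained_probes": self.retained_probes,
        }

    def write(self, path: str | pathlib.Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=bool)


def copy_threshold(matrix: ExpressionMatrix, spike20_probe: str = DEFAULT_SPIKE20) -> float:
    """Median signal of the 20-copy spike probe across all cells."""
    if spike20_probe not in matrix.values.index:
        raise KeyError(f"spike probe not in matrix: {spike20_probe}")
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative signal intensities: corrupt input")
    return float(np.median(matrix.values.loc[spike20_probe].to_numpy()))


def filter_detected(matrix, threshold: float) -> list[str]:
    """Probe ids whose maximum signal over cells is >= threshold.

    Accepts an :class:`ExpressionMatrix` or a plain probes x cells frame;
    input probe order is preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    keep = values.max(axis=1) >= threshold
    return list(values.index[keep])


def spike_linearity(
    matrix: ExpressionMatrix,
    spikeins: Sequence[tuple[str, float]],
    tol: float = 0.25,
) -> pd.DataFrame:
    """Per-sample OLS of log2(signal) on log2(copies), spikes >= 20 copies only.

    Returns a frame indexed by cell id with columns ``slope``, ``r2`` and
    ``flagged`` (slope outside [1 - tol, 1 + tol]).
    """
    usable = [(p, c) for p, c in spikeins if c >= 20]
    if len({c for _, c in usable}) < 2:
        raise ValueError("need >= 2 distinct spike copy levels >= 20")
    probes = [p for p, _ in usable]
    missing = set(probes) - set(matrix.values.index)
    if missing:
        raise KeyError(f"spike probes not in matrix: {sorted(missing)}")
    x = np.log2([c for _, c in usable])
    sig = matrix.values.loc[probes].to_numpy(float)
    with np.errstate(divide="ignore"):
        y = np.log2(np.clip(sig, 1e-12, None))

    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    sxx = float((xc**2).sum())
    slope = (xc[:, None] * yc).sum(axis=0) / sxx
    ss_res = ((yc - slope[None, :] * xc[:, None]) ** 2).sum(axis=0)
    ss_tot = (yc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    flagged = np.abs(slope - 1.0) > tol
    return pd.DataFrame(
        {"slope": slope, "r2": r2, "flagged": flagged},
        index=matrix.values.columns,
    )


def sample_qc(
    data: ExpressionMatrix | QpcrTable,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
    threshold: float | None = None,
    spikeins: Sequence[tuple[str, float]] | None = None,
    tol: float = 0.25,
) -> tuple[dict[str, bool], dict[str, list[str]]]:
    """Pass/fail per sample with failure reasons.

    A sample passes iff every housekeeping gene is detected (signal >=
    ``threshold`` on arrays, Ct < 40 on qPCR) and, when spike-ins are
    given for an array matrix, its spike linearity flag is clear.
    """
    if not housekeeping:
        raise ValueError("housekeeping gene list is empty")
    reasons: dict[str, list[str]] = {}

    if isinstance(data, QpcrTable):
        missing = set(housekeeping) - set(data.ct.index)
        if missing:
            raise KeyError(f"housekeeping genes not measured: {sorted(missing)}")
        detected = data.detected.loc[list(housekeeping)]
        cells = data.cell_ids
    else:
        if threshold is None:
            raise ValueError("threshold required for array matrices")
        probes = data.symbols_to_probes(housekeeping)
        detected = data.values.loc[probes] >= threshold
        detected.index = list(housekeeping)
        cells = data.cell_ids

    for cell in cells:
        rs = [
            f"housekeeping undetected: {gene}"
            for gene in housekeeping
            if not bool(detected.loc[gene, cell])
        ]
        reasons[cell] = rs

    if spikeins is not None and isinstance(data, ExpressionMatrix):
        fits = spike_linearity(data, spikeins, tol=tol)
        for cell in cells:
            if bool(fits.loc[cell, "flagged"]):
                reasons[cell].append(
                    f"spike slope out of range: {fits.loc[cell, 'slope']:.3f}"
                )

    passed = {cell: not reasons[cell] for cell in cells}
    return passed, reasons


def run_qc(
    matrix: ExpressionMatrix,
    spike20_probe: str = DEFAULT_SPIKE20,
    spikeins: Sequence[tuple[str, float]] | None = None,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
    tol: float = 0.25,
) -> QcReport:
    """Full QC pipeline: sample QC, threshold from passing cells, probe filter.

    The spike median is computed over cells passing sample QC only, so a
    failed amplification cannot bias the detection threshold.
    """
    if spikeins is None:
        spk = matrix.probes["spike_copies"].dropna()
        spikeins = [(p, float(c)) for p, c in spk.items()]
    # first pass: any positive signal counts as detected, to pick the cells
    # whose spike median defines the calibrated threshold
    passed, reasons = sample_qc(
        matrix, housekeeping, threshold=np.finfo(float).tiny,
        spikeins=spikeins, tol=tol,
    )
    good_cells = [c for c, ok in passed.items() if ok]
    sub = matrix.subset(cells=good_cells) if good_cells else matrix
    thr = copy_threshold(sub, spike20_probe)
    # re-run housekeeping detection against the calibrated threshold
    passed, reasons = sample_qc(
        matrix, housekeeping, threshold=thr, spikeins=spikeins, tol=tol
    )
    good_cells = [c for c, ok in passed.items() if ok]
    sub = matrix.subset(cells=good_cells) if good_cells else matrix
    thr = copy_threshold(sub, spike20_probe)
    retained = filter_detected(sub, thr)
    fits = spike_linearity(matrix, spikeins, tol=tol)
    return QcReport(
        copy_threshold=thr,
        spike_fits=fits,
        sample_pass=passed,
        reasons=reasons,
        retained_probes=retained,
    )
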