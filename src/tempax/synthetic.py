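"""Synthetic single-cell expression and qPCR data with known latent structure.

Two latent coordinates drive every non-spike, non-marker gene: a temporal
coordinate tau (monotone in developmental stage) and a differentiation
coordinate delta (cell type). Log2 signal of gene g in cell i is

    baseline_g + a_g * tau_i + b_g * delta_i + cyc_g * cycling_i + noise

and linear signal is ``2 ** log2_signal``.  Temporal effects ``a_g`` are
shared across cell types, so temporal shifts are parallel between cell
types by construction.  Spike-in probes depend only on their nominal copy
number: proportional signal at >= 20 copies, inflated noise plus Bernoulli
dropout below.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import UNDETECTED_CT, ExpressionMatrix, QpcrTable

WILD_TYPE = "wild-type"
ARREST_MODES = ("NICD", "NICD+p18", "clonal-arrest")

GENE_CLASSES = (
    "temporal",
    "differentiation",
    "cellcycle",
    "housekeeping",
    "marker",
    "spike",
)

#: Spike-in probe ids with nominal copies per cell (lys/dap/phe/thr design).
DEFAULT_SPIKEINS = (
    ("AFFX-r2-Bs-lys-3_at", 1000.0),
    ("AFFX-r2-Bs-dap-3_at", 100.0),
    ("AFFX-r2-Bs-phe-3_at", 20.0),
    ("AFFX-r2-Bs-thr-3_at", 5.0),
)

#: 18-gene temporal panel: early-high genes fall with tau, late-high rise.
EARLY_HIGH_GENES = (
    "Dmrt3", "Dmrta1", "Sulf2", "Crabp2", "Lrrn1",
    "Fndc3c1", "Flrt3", "Hmga2", "Sema5a",
)
LATE_HIGH_GENES = (
    "Zbtb20", "Rlbp1", "Aldoc", "Ptn", "Pag1",
    "Tgfb2", "Nfia", "Fabp7", "Sparc",
)
TEMPORAL_PANEL = EARLY_HIGH_GENES + LATE_HIGH_GENES

HOUSEKEEPING_GENES = ("Gapdh", "Actb", "Aldoa", "Pabpn1")

#: Marker gene model: (symbol, types, conditions, requires_cycling).
#: Empty type/condition tuples mean "no restriction on that attribute".
MARKER_SPECS = (
    ("Ki67", (), (), True),
    ("Ttyh1", ("AP",), (), False),
    ("Tbr2", ("IP",), (), False),
    ("Egfp", (), ("NICD", "NICD+p18", "clonal-arrest"), False),
)


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


def _stage_tau_from_labels(stages: Sequence[str]) -> dict[str, float]:
    """Equally spaced clock per embryonic day: E10 -> 0 ... E16 -> 6."""
    taus = {}
    for i, s in enumerate(stages):
        m = re.fullmatch(r"E(\d+(?:\.\d+)?)", s)
        taus[s] = float(m.group(1)) - 10.0 if m else float(i)
    return taus


@dataclasses.dataclass
class SimConfig:
    """Configuration for the synthetic study design."""

    stages: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"E11": 30, "E14": 70, "E16": 28}
    )
    stage_tau: dict[str, float] | None = None
    mixing: dict[str, dict[str, float]] | None = None
    type_delta: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"AP": 0.0, "IP": 2.0, "neuron": 4.0}
    )
    n_temporal: int = 40
    n_differentiation: int = 30
    n_cellcycle: int = 15
    n_housekeeping: int = 15
    temporal_effect: float = 1.0
    diff_effect: float = 1.0
    cycle_effect: float = 2.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    marker_baseline: float = 11.0
    noise_sd: float = 0.5
    spikeins: tuple[tuple[str, float], ...] = DEFAULT_SPIKEINS
    spike_unit: float = 43.51
    spike_noise_sd: float = 0.1
    sub20_noise_factor: float = 3.0
    sub20_dropout: float = 0.5
    qpcr_c0: float = 38.0
    qpcr_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage_tau is None:
            self.stage_tau = _stage_tau_from_labels(list(self.stages))
        if self.mixing is None:
            self.mixing = {
                s: {"AP": 0.6, "IP": 0.3, "neuron": 0.1} for s in self.stages
            }
        self.validate()

    def validate(self) -> None:
        taus = [self.stage_tau[s] for s in self.stages]
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ConfigurationError(
                f"stage->tau map must be strictly increasing, got {taus}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for pid, copies in self.spikeins:
            if copies <= 0:
                raise ConfigurationError(f"spike {pid} has non-positive copies")
        for stage, mix in self.mixing.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"mixing proportions at {stage} sum to {total}, not 1"
                )
            unknown = set(mix) - set(self.type_delta)
            if unknown:
                raise ConfigurationError(f"unknown cell types {sorted(unknown)}")
        if not 0.0 <= self.sub20_dropout <= 1.0:
            raise ConfigurationError("sub20_dropout must be in [0, 1]")

    @property
    def n_genes(self) -> int:
        return (
            self.n_temporal
            + self.n_differentiation
            + self.n_cellcycle
            + self.n_housekeeping
            + len(MARKER_SPECS)
            + len(self.spikeins)
        )

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spikeins" in raw:
            raw["spikeins"] = tuple(
                (str(p), float(c)) for p, c in raw["spikeins"]
            )
        return cls(**raw)


def study_config(**overrides) -> SimConfig:
    """Config mirroring the study's array design (E11/E14/E16, 30/70/28)."""
    return SimConfig(**overrides)


def qpcr_config(**overrides) -> SimConfig:
    """Config mirroring the qPCR design: wild-type APs pooled over E10-E14."""
    defaults = dict(
        stages={"E10": 18, "E11": 24, "E12": 21, "E13": 21, "E14": 18},
        mixing=None,
    )
    defaults.update(overrides)
    cfg = SimConfig(**defaults)
    return cfg


@dataclasses.dataclass
class GroundTruth:
    """Latent per-cell and per-gene quantities behind a simulated dataset."""

    cells: pd.DataFrame  # stage, cell_type, condition, tau, delta, cycling, frozen_tau
    genes: pd.DataFrame  # symbol, gene_class, baseline, a, b, cyc, spike_copies, ...
    frozen_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        arrested = self.cells["condition"].isin(["NICD+p18", "clonal-arrest"])
        if bool((arrested & self.cells["cycling"]).any()):
            raise ValueError("cell-cycle-arrested cells must have cycling=False")
        classes = set(self.genes["gene_class"])
        unknown = classes - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            cells=self.cells.copy(),
            genes=self.genes.copy(),
            frozen_genes=self.frozen_genes,
        )

    def probes_for(self, symbols: Iterable[str]) -> list[str]:
        lookup: dict[str, str] = {}
        for pid, sym in sorted(self.genes["symbol"].items()):
            lookup.setdefault(sym, pid)
        out = []
        for sym in symbols:
            if sym not in lookup:
                raise KeyError(f"gene not in ground truth: {sym}")
            out.append(lookup[sym])
        return out

    def write(self, path: str | pathlib.Path) -> None:
        payload = {
            "cells": self.cells.rename_axis("cell_id").reset_index().to_dict(
                orient="records"
            ),
            "genes": self.genes.rename_axis("probe_id").reset_index().to_dict(
                orient="records"
            ),
            "frozen_genes": sorted(self.frozen_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _build_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows: list[dict] = []

    def add(pid, symbol, gene_class, baseline, a=0.0, b=0.0, cyc=0.0,
            spike_copies=np.nan, marker_types="", marker_conditions="",
            requires_cycling=False):
        rows.append(
            dict(probe_id=pid, symbol=symbol, gene_class=gene_class,
                 baseline=baseline, a=a, b=b, cyc=cyc,
                 spike_copies=spike_copies, marker_types=marker_types,
                 marker_conditions=marker_conditions,
                 requires_cycling=requires_cycling)
        )

    # Temporal genes: first 18 named after the panel, early-high negative a.
    for i in range(config.n_temporal):
        if i < len(TEMPORAL_PANEL):
            sym = TEMPORAL_PANEL[i]
            sign = -1.0 if sym in EARLY_HIGH_GENES else 1.0
        else:
            sym = f"Tmp{i:03d}"
            sign = -1.0 if i % 2 else 1.0
        mag = config.temporal_effect * rng.uniform(0.8, 1.2)
        add(f"T{i:04d}_at", sym, "temporal",
            config.baseline_mean + rng.normal(0, config.baseline_sd),
            a=sign * mag)
    for i in range(config.n_differentiation):
        sign = -1.0 if i % 2 else 1.0
        mag = config.diff_effect * rng.uniform(0.8, 1.2)
        add(f"D{i:04d}_at", f"Dif{i:03d}", "differentiation",
            config.baseline_mean + rng.normal(0, config.baseline_sd),
            b=sign * mag)
    for i in range(config.n_cellcycle):
        add(f"C{i:04d}_at", f"Ccn{i:03d}", "cellcycle",
            config.baseline_mean - 2.0 + rng.normal(0, config.baseline_sd),
            cyc=config.cycle_effect * rng.uniform(0.8, 1.2))
    for i in range(config.n_housekeeping):
        sym = (HOUSEKEEPING_GENES[i] if i < len(HOUSEKEEPING_GENES)
               else f"Hkg{i:03d}")
        add(f"H{i:04d}_at", sym, "housekeeping",
            config.baseline_mean + 4.0
            + rng.normal(0, min(config.baseline_sd, 0.5)))
    for i, (sym, types, conds, req_cyc) in enumerate(MARKER_SPECS):
        add(f"M{i:04d}_at", sym, "marker", config.marker_baseline,
            marker_types="|".join(types), marker_conditions="|".join(conds),
            requires_cycling=req_cyc)
    for pid, copies in config.spikeins:
        add(pid, pid, "spike", np.nan, spike_copies=copies)

    genes = pd.DataFrame(rows).set_index("probe_id")
    return genes


def build_truth(config: SimConfig) -> GroundTruth:
    """Assign cells to stages/types and draw per-gene effect sizes."""
    rng = _rng(config.seed, 0)
    genes = _build_genes(config, rng)

    records = []
    counter = 0
    for stage, n in config.stages.items():
        mix = config.mixing[stage]
        types = sorted(mix)
        counts = np.floor(np.array([mix[t] for t in types]) * n).astype(int)
        # distribute rounding remainder deterministically by largest fraction
        frac = np.array([mix[t] for t in types]) * n - counts
        for j in np.argsort(-frac)[: n - counts.sum()]:
            counts[j] += 1
        tau = config.stage_tau[stage]
        for t, c in zip(types, counts):
            for _ in range(c):
                records.append(
                    dict(cell_id=f"c{counter:04d}_{stage}", stage=stage,
                         cell_type=t, condition=WILD_TYPE, tau=tau,
                         delta=config.type_delta[t],
                         cycling=t != "neuron", frozen_tau=np.nan)
                )
                counter += 1
    cells = pd.DataFrame(records).set_index("cell_id")
    return GroundTruth(cells=cells, genes=genes)


def apply_arrest(
    truth: GroundTruth,
    cells: Sequence[str],
    mode: str,
    freeze_genes: Sequence[str] = (),
    arrest_tau: float | None = None,
) -> GroundTruth:
    """Mark cells as perturbed; the temporal clock keeps advancing.

    ``NICD`` only relabels the condition. ``NICD+p18`` additionally stops
    cycling (silencing cell-cycle genes and the cycling-gated markers).
    ``clonal-arrest`` stops cycling and freezes the listed temporal genes
    at ``arrest_tau``, emulating a partial, cell-intrinsic-only transition.
    """
    if mode not in ARREST_MODES:
        raise ValueError(f"unknown arrest mode {mode!r}; expected {ARREST_MODES}")
    missing = set(cells) - set(truth.cells.index)
    if missing:
        raise KeyError(f"unknown cells: {sorted(missing)}")
    out = truth.copy()
    idx = list(cells)
    out.cells.loc[idx, "condition"] = mode
    if mode in ("NICD+p18", "clonal-arrest"):
        out.cells.loc[idx, "cycling"] = False
    frozen = set(out.frozen_genes)
    if mode == "clonal-arrest" and freeze_genes:
        if arrest_tau is None:
            raise ValueError("clonal-arrest with freeze_genes needs arrest_tau")
        probes = out.probes_for(freeze_genes)
        bad = [
            p for p in probes if out.genes.loc[p, "gene_class"] != "temporal"
        ]
        if bad:
            raise ValueError(f"can only freeze temporal genes, got {bad}")
        frozen.update(probes)
        out.cells.loc[idx, "frozen_tau"] = arrest_tau
    return GroundTruth(cells=out.cells, genes=out.genes,
                       frozen_genes=frozenset(frozen))


def expected_log2(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Noise-free expected log2 signal; -inf encodes zero linear signal."""
    genes, cells = truth.genes, truth.cells
    n_g, n_c = len(genes), len(cells)
    out = np.full((n_g, n_c), -np.inf)

    tau = cells["tau"].to_numpy(float)
    delta = cells["delta"].to_numpy(float)
    cycling = cells["cycling"].to_numpy(bool).astype(float)
    frozen_tau = cells["frozen_tau"].to_numpy(float)

    for gi, (pid, g) in enumerate(genes.iterrows()):
        cls = g["gene_class"]
        if cls == "spike":
            out[gi, :] = np.log2(g["spike_copies"] * config.spike_unit)
        elif cls == "temporal":
            t_eff = tau
            if pid in truth.frozen_genes:
                t_eff = np.where(np.isnan(frozen_tau), tau, frozen_tau)
            out[gi, :] = g["baseline"] + g["a"] * t_eff
        elif cls == "differentiation":
            out[gi, :] = g["baseline"] + g["b"] * delta
        elif cls == "cellcycle":
            out[gi, :] = g["baseline"] + g["cyc"] * cycling
        elif cls == "housekeeping":
            out[gi, :] = g["baseline"]
        elif cls == "marker":
            expressed = np.ones(n_c, bool)
            if g["marker_types"]:
                allowed = set(g["marker_types"].split("|"))
                expressed &= cells["cell_type"].isin(allowed).to_numpy()
            if g["marker_conditions"]:
                allowed = set(g["marker_conditions"].split("|"))
                expressed &= cells["condition"].isin(allowed).to_numpy()
            if g["requires_cycling"]:
                expressed &= cycling.astype(bool)
            out[gi, expressed] = g["baseline"]
    return pd.DataFrame(out, index=genes.index, columns=cells.index)


def realize_expression(
    truth: GroundTruth, config: SimConfig, seed: int | None = None
) -> ExpressionMatrix:
    """Draw one noisy linear-scale expression matrix from the truth."""
    rng = _rng(config.seed if seed is None else seed, 1)
    exp = expected_log2(truth, config).to_numpy()
    genes = truth.genes
    is_spike = (genes["gene_class"] == "spike").to_numpy()
    copies = genes["spike_copies"].to_numpy(float)

    sd = np.full(len(genes), config.noise_sd)
    sd[is_spike] = config.spike_noise_sd
    sub20 = is_spike & (copies < 20)
    sd[sub20] = config.spike_noise_sd * config.sub20_noise_factor

    noise = rng.normal(0.0, 1.0, size=exp.shape) * sd[:, None]
    with np.errstate(invalid="ignore"):
        log2sig = exp + noise
    linear = np.where(np.isneginf(exp), 0.0, np.exp2(log2sig))

    if sub20.any() and config.sub20_dropout > 0:
        drop = rng.random(size=exp.shape) < config.sub20_dropout
        linear[sub20[:, None] & drop] = 0.0

    values = pd.DataFrame(
        linear, index=truth.genes.index, columns=truth.cells.index
    )
    probes = truth.genes[["symbol", "gene_class", "spike_copies"]].copy()
    cells = truth.cells[["stage", "cell_type", "condition"]].copy()
    return ExpressionMatrix(values=values, probes=probes, cells=cells)


def simulate_dataset(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Build the ground truth and one expression matrix realization."""
    truth = build_truth(config)
    return realize_expression(truth, config), truth


def simulate_qpcr(
    truth: GroundTruth,
    panel: Sequence[str],
    config: SimConfig,
    seed: int | None = None,
) -> QpcrTable:
    """qPCR readout: Ct = C0 - log2(expected linear signal) + noise.

    Ct values are clipped to [0, 40]; 40 is recorded for zero expected
    signal and flags the measurement as undetected.
    """
    if "Gapdh" not in panel:
        raise ValueError("panel must include the reference gene Gapdh")
    probes = truth.probes_for(panel)  # raises naming the missing gene
    rng = _rng(config.seed if seed is None else seed, 2)
    exp = expected_log2(truth, config).loc[probes].to_numpy()
    noise = rng.normal(0.0, config.qpcr_noise_sd, size=exp.shape)
    with np.errstate(invalid="ignore"):
        ct = config.qpcr_c0 - exp + noise
    ct = np.where(np.isneginf(exp), UNDETECTED_CT, ct)
    ct = np.clip(ct, 0.0, UNDETECTED_CT)
    return QpcrTable(
        ct=pd.DataFrame(ct, index=list(panel), columns=truth.cells.index)
    )
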