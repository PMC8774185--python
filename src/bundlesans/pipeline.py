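"""Per-condition analysis pipeline and solution-state assignment.

Runs the full dilute-solution workup for each sample condition — Guinier,
Kratky, P(r), a shape-model fit (Debye coil and/or joint-clubs), and the
molecular-weight ratio against a designated standard condition — then
assigns a coarse solution state from the quantitative evidence:

    MW ratio >= 1.7 and Kratky "folded"              -> folded_dimer
    MW ratio <= 1.3 and Kratky "random_coil"         -> random_coil
    MW ratio <= 1.3 and Kratky "partially_flexible"
        and joint-clubs chi^2 < Debye chi^2          -> open_bundle_monomer
    otherwise                                        -> folded_mixed

The ratio bands (<= 1.3 monomer-like, >= 1.7 dimer-like) discretize the
observed clustering of I(0)/C ratios around 1 and 2; both are parameters.
Reports are deterministic: the same config and seed yield byte-identical
JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from . import model_free, pr_inversion
from .joint_clubs import JointClubsParams, joint_clubs_fit
from .sas_io import ScatteringCurve, read_curve

__all__ = ["ConditionConfig", "ConditionResult", "StateReport",
           "run_pipeline", "load_conditions"]

log = logging.getLogger("bundlesans.pipeline")

MONOMER_RATIO_MAX = 1.3
DIMER_RATIO_MIN = 1.7


@dataclass
class ConditionConfig:
    """One sample condition: its curve, metadata and analysis windows."""
    curve: Union[str, Path, ScatteringCurve]
    label: str
    concentration: float
    guinier_q2_range: Tuple[float, float] = model_free.DEFAULT_Q2_WINDOW
    pr_q_range: Tuple[float, float] = pr_inversion.DEFAULT_Q_RANGE
    model: str = "none"            # "debye" | "joint_clubs" | "none"
    dmax: float = 60.0
    is_standard: bool = False
    jc_init: Optional[JointClubsParams] = None
    n_conformations: int = 2000

    def load_curve(self) -> ScatteringCurve:
        if isinstance(self.curve, ScatteringCurve):
            return self.curve
        return read_curve(self.curve)


@dataclass
class ConditionResult:
    label: str
    guinier: Optional[model_free.GuinierResult] = None
    kratky: Optional[model_free.KratkyProfile] = None
    pr: Optional[pr_inversion.PrResult] = None
    debye: Optional[model_free.DebyeResult] = None
    joint_clubs: Optional[object] = None
    mw: Optional[model_free.MwRatioResult] = None
    state: str = "unassigned"
    evidence: List[str] = field(default_factory=list)
    errors: List[str] = field(default_factory=list)


@dataclass
class StateReport:
    conditions: List[ConditionResult]
    standard_label: str
    seed: int

    def to_dict(self) -> Dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return None  # arrays (profiles) are not serialized
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return {
            "standard": self.standard_label,
            "seed": self.seed,
            "conditions": [clean(c) for c in self.conditions],
        }

    def to_json(self) -> str:
        """Deterministic JSON (sorted keys, fixed float repr)."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def states(self) -> Dict[str, str]:
        return {c.label: c.state for c in self.conditions}


def _assign_state(res: ConditionResult,
                  monomer_max: float = MONOMER_RATIO_MAX,
                  dimer_min: float = DIMER_RATIO_MIN) -> None:
    evidence = []
    ratio = res.mw.ratio if res.mw is not None else None
    kratky_cls = res.kratky.classification if res.kratky is not None else None
    if ratio is not None:
        evidence.append(f"MW ratio vs standard = {ratio:.2f}")
    if kratky_cls is not None:
        evidence.append(f"Kratky classification: {kratky_cls}")
    jc_better = None
    if res.joint_clubs is not None and res.debye is not None:
        jc_better = res.joint_clubs.chi2_reduced < res.debye.chi2_reduced
        evidence.append(
            f"joint-clubs chi2_red = {res.joint_clubs.chi2_reduced:.3g} vs "
            f"Debye chi2_red = {res.debye.chi2_reduced:.3g}")
    if res.guinier is not None:
        evidence.append(f"Guinier Rg = {res.guinier.rg:.2f} A")

    if ratio is None or kratky_cls is None:
        res.state = "folded_mixed"
        res.evidence = evidence + ["insufficient evidence; defaulted"]
        return
    if ratio >= dimer_min and kratky_cls == "folded":
        res.state = "folded_dimer"
    elif ratio <= monomer_max and kratky_cls == "random_coil":
        res.state = "random_coil"
    elif (ratio <= monomer_max and kratky_cls == "partially_flexible"
          and jc_better):
        res.state = "open_bundle_monomer"
    else:
        res.state = "folded_mixed"
    res.evidence = evidence


def run_pipeline(conditions: Sequence[ConditionConfig],
                 seed: int = 0,
                 monomer_ratio_max: float = MONOMER_RATIO_MAX,
                 dimer_ratio_min: float = DIMER_RATIO_MIN) -> StateReport:
    """Run every analysis stage for each condition and assign states.

    Exactly one condition must have ``is_standard=True``; its I(0)/C from
    the Guinier fit anchors the molecular-weight ratios.  Stage failures
    are recorded per condition and the pipeline continues.
    """
    if len(conditions) == 0:
        raise ValueError("need at least one condition")
    standards = [c for c in conditions if c.is_standard]
    if len(standards) != 1:
        raise ValueError(f"exactly one condition must be the standard; "
                         f"found {len(standards)}")
    standard = standards[0]

    results: List[ConditionResult] = []
    curves: Dict[str, ScatteringCurve] = {}
    for cfg in conditions:
        res = ConditionResult(label=cfg.label)
        try:
            curve = cfg.load_curve()
            curves[cfg.label] = curve
        except Exception as exc:
            res.errors.append(f"load: {exc}")
            results.append(res)
            continue
        log.info("condition %s: n=%d points, windows guinier=%s pr=%s "
                 "model=%s seed=%d", cfg.label, len(curve),
                 cfg.guinier_q2_range, cfg.pr_q_range, cfg.model, seed)
        for stage, fn in (
            ("guinier", lambda: model_free.guinier_fit(
                curve, *cfg.guinier_q2_range, enforce_qrg=False)),
            ("kratky", lambda: model_free.kratky_transform(curve)),
            ("pr", lambda: pr_inversion.ift(
                curve, dmax=cfg.dmax, q_range=cfg.pr_q_range)),
        ):
            try:
                setattr(res, stage, fn())
            except Exception as exc:
                res.errors.append(f"{stage}: {exc}")
        if cfg.model in ("debye", "joint_clubs"):
            try:
                res.debye = model_free.debye_fit(curve)
            except Exception as exc:
                res.errors.append(f"debye: {exc}")
        if cfg.model == "joint_clubs":
            try:
                res.joint_clubs = joint_clubs_fit(
                    curve, init=cfg.jc_init,
                    n_conformations=cfg.n_conformations, seed=seed)
            except Exception as exc:
                res.errors.append(f"joint_clubs: {exc}")
        results.append(res)

    # molecular-weight ratios against the standard's Guinier I(0)
    std_res = next(r for r in results if r.label == standard.label)
    if std_res.guinier is not None:
        i0_st, c_st = std_res.guinier.i0, standard.concentration
        for cfg, res in zip(conditions, results):
            if res.guinier is None:
                continue
            try:
                res.mw = model_free.mw_ratio(res.guinier.i0,
                                             cfg.concentration, i0_st, c_st)
            except ValueError as exc:
                res.errors.append(f"mw_ratio: {exc}")
    else:
        for res in results:
            res.errors.append("mw_ratio: standard condition has no Guinier fit")

    for res in results:
        _assign_state(res, monomer_ratio_max, dimer_ratio_min)
    return StateReport(conditions=results, standard_label=standard.label,
                       seed=seed)


def load_conditions(path: Union[str, Path]) -> List[ConditionConfig]:
    """Load a list of :class:`ConditionConfig` from a YAML file.

    Layout::

        standard: "pD 1.7"
        conditions:
          - label: "pD 1.7"
            curve: data/pd17.dat
            concentration: 5.5
            model: debye
            dmax: 90
            guinier_q2_range: [0.001, 0.002]
            pr_q_range: [0.05, 0.25]
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    std = doc.get("standard")
    base = Path(path).parent
    out = []
    for entry in doc["conditions"]:
        curve = entry["curve"]
        if not Path(curve).is_absolute():
            curve = base / curve
        out.append(ConditionConfig(
            curve=curve, label=entry["label"],
            concentration=float(entry["concentration"]),
            guinier_q2_range=tuple(entry.get("guinier_q2_range",
                                             model_free.DEFAULT_Q2_WINDOW)),
            pr_q_range=tuple(entry.get("pr_q_range",
                                       pr_inversion.DEFAULT_Q_RANGE)),
            model=entry.get("model", "none"),
            dmax=float(entry.get("dmax", 60.0)),
            is_standard=(entry["label"] == std) or entry.get("standard", False),
        ))
    return out
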