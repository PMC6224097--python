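"""End-to-end analysis pipeline over outcomes, scenarios and strata.

For each outcome (facility delivery on the 5-year window with multiple
births collapsed to one delivery; neonatal mortality on the 10-year window
with multiples kept) and each exposure scenario, the pipeline selects the
analysis window, tests the subsidy interactions (jointly, then separately),
stratifies by residence when the subsidy x rural interaction is significant
for the delivery outcome, fits the segmented multilevel Poisson model,
predicts random effects by empirical Bayes and standardizes to marginal
RR/RD grids.  Failures in any cell are recorded and the run continues.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PopulationConfig
from .model import (ITSResults, LRTResult, ModelSpec, MultilevelPoissonITS,
                    lrt, vif)
from .records_io import (CharacteristicsTable, FlowCounts,
                         characteristics_table, collapse_deliveries,
                         flow_accounting)
from .scenarios import ExposureScenario, apply_scenario
from .standardize import DEFAULT_HORIZONS, standardize

INTERACTION_TERMS = ("subsidy_x_rural", "subsidy_x_wealth",
                     "subsidy_x_education")


@dataclass
class AnalysisOptions:
    """Pipeline settings (windows, model layout, which stages to run)."""

    survey_month: int = 132
    window_5yr: int = 60
    window_10yr: int = 120
    scenarios: Sequence[str] = ("primary", "shift_april", "exclude_q1")
    outcomes: Sequence[str] = ("delivery", "mortality")
    horizons: Sequence[int] = DEFAULT_HORIZONS
    random_terms: Sequence[str] = ("intercept", "subsidy")
    n_levels: Dict[str, int] = field(
        default_factory=lambda: {"delivery": 2, "mortality": 3})
    fixed_terms: Sequence[str] = ModelSpec.fixed_terms
    quadrature_nodes: int = 5
    do_interactions: bool = True
    stratify_by_rural: str = "auto"   # auto | never | always
    alpha: float = 0.05
    fit_restarts: int = 1
    fit_maxiter: int = 300

    @classmethod
    def from_yaml(cls, path) -> "AnalysisOptions":
        """Read the model / scenario / reporting blocks of an analysis
        config (unknown keys rejected; missing blocks keep defaults)."""
        import yaml
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        kw = {}
        for block in ("model", "scenario", "reporting"):
            kw.update(payload.get(block, {}))
        valid = {f.name for f in fields(cls)}
        unknown = set(kw) - valid
        if unknown:
            raise ValueError(f"unknown analysis option(s): {sorted(unknown)}")
        for key in ("scenarios", "outcomes", "horizons", "random_terms",
                    "fixed_terms"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass
class InteractionDecision:
    joint: Optional[LRTResult]
    separate: Dict[str, LRTResult]
    stratify: bool
    base_fit: Optional[ITSResults] = None


@dataclass
class StratumResult:
    fit: Optional[ITSResults] = None
    grid: Optional[object] = None
    vif: Optional[pd.Series] = None
    error: Optional[str] = None


@dataclass
class AnalysisCell:
    outcome: str
    scenario: str
    n_records: int
    excluded: int
    interactions: Optional[InteractionDecision]
    strata: Dict[str, StratumResult]
    error: Optional[str] = None


@dataclass
class AnalysisReport:
    config_hash: str
    seed: Optional[int]
    flow: FlowCounts
    characteristics: Dict[str, CharacteristicsTable]
    cells: Dict[Tuple[str, str], AnalysisCell]

    def to_dict(self) -> dict:
        out = {"config_hash": self.config_hash, "seed": self.seed,
               "flow": self.flow.__dict__,
               "characteristics": {k: json.loads(v.to_json())
                                   for k, v in self.characteristics.items()},
               "cells": {}}
        for (oc, sc), cell in self.cells.items():
            c = {"n_records": cell.n_records, "excluded": cell.excluded,
                 "error": cell.error, "strata": {}}
            if cell.interactions is not None:
                c["interactions"] = {
                    "stratify": cell.interactions.stratify,
                    "joint": (cell.interactions.joint.__dict__
                              if cell.interactions.joint else None),
                    "separate": {k: v.__dict__ for k, v in
                                 cell.interactions.separate.items()}}
            for name, sr in cell.strata.items():
                c["strata"][name] = {
                    "error": sr.error,
                    "fit": sr.fit.to_dict() if sr.fit else None,
                    "grid": (json.loads(sr.grid.to_json())
                             if sr.grid is not None else None),
                    "vif": sr.vif.to_dict() if sr.vif is not None else None}
            out["cells"][f"{oc}/{sc}"] = c
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=float)


def select_window(records: pd.DataFrame, outcome: str,
                  opts: AnalysisOptions) -> pd.DataFrame:
    """Outcome analysis window; collapses multiples for the delivery outcome."""
    bm = records["birth_month"]
    if outcome == "delivery":
        win = records[(bm >= opts.survey_month - opts.window_5yr)
                      & (bm < opts.survey_month)]
        return collapse_deliveries(win)
    return records[(bm >= opts.survey_month - opts.window_10yr)
                   & (bm < opts.survey_month)]


def interaction_analysis(records: pd.DataFrame, spec: ModelSpec,
                         scenario: ExposureScenario,
                         opts: Optional[AnalysisOptions] = None,
                         **fit_kw) -> InteractionDecision:
    """LRTs of the subsidy interactions, jointly then separately.

    Stratification by residence is recommended when the subsidy x rural
    interaction is significant for the delivery outcome.
    """
    opts = opts or AnalysisOptions()
    base_terms = tuple(t for t in spec.fixed_terms
                       if t not in INTERACTION_TERMS)
    spec0 = replace(spec, fixed_terms=base_terms)
    full_terms = base_terms + INTERACTION_TERMS
    spec_all = replace(spec, fixed_terms=full_terms)
    r0 = MultilevelPoissonITS.from_records(records, spec0, scenario).fit(**fit_kw)
    # keep the interaction fits on the random structure the base fit settled
    # on (boundary collapses propagate, so the LRTs compare like with like)
    rspec = r0.bundle.spec
    spec_all = replace(spec_all, random_terms=rspec.random_terms,
                       n_levels=rspec.n_levels)
    spec = replace(spec, random_terms=rspec.random_terms,
                   n_levels=rspec.n_levels)
    m_all = MultilevelPoissonITS.from_records(records, spec_all, scenario)
    r_all = m_all.fit(start=_warm_start(m_all, r0), **fit_kw)
    joint = lrt(r0, r_all)
    separate = {}
    for term in INTERACTION_TERMS:
        spec1 = replace(spec, fixed_terms=base_terms + (term,))
        m1 = MultilevelPoissonITS.from_records(records, spec1, scenario)
        r1 = m1.fit(start=_warm_start(m1, r0), **fit_kw)
        separate[term] = lrt(r0, r1)
    stratify = (spec.outcome == "delivery"
                and separate["subsidy_x_rural"].p_value < opts.alpha)
    return InteractionDecision(joint=joint, separate=separate,
                               stratify=stratify, base_fit=r0)


def _warm_start(model: MultilevelPoissonITS,
                ref: ITSResults) -> Optional[np.ndarray]:
    """Start vector for a model nesting an already-fitted one."""
    lay = model.layout
    if lay.size == lay.p:
        return None
    th = lay.pack_start(np.zeros(lay.p))
    for i, n in enumerate(model.bundle.xnames):
        if n in ref.params.index:
            th[i] = ref.params[n]
    ref_lay = ref.model.layout
    if lay.size - lay.p == ref_lay.size - ref_lay.p:
        th[lay.p:] = ref.theta[ref_lay.p:]
    return th


def _stratum_spec(spec: ModelSpec, stratum: str) -> ModelSpec:
    if stratum == "pooled":
        return spec
    terms = tuple(t for t in spec.fixed_terms
                  if t not in ("rural", "subsidy_x_rural"))
    return replace(spec, fixed_terms=terms)


def run_analysis(records: pd.DataFrame, config: Optional[PopulationConfig],
                 opts: Optional[AnalysisOptions] = None) -> AnalysisReport:
    """Full analysis: windows, scenarios, interactions, fits, standardization."""
    opts = opts or AnalysisOptions()
    flow = flow_accounting(records, opts.survey_month,
                           window_5yr=opts.window_5yr,
                           window_10yr=opts.window_10yr)
    chars = {}
    ten_yr = records[(records["birth_month"] >= opts.survey_month
                      - opts.window_10yr)
                     & (records["birth_month"] < opts.survey_month)]
    for name in opts.scenarios:
        chars[name] = characteristics_table(ten_yr,
                                            ExposureScenario.from_name(name))

    cells: Dict[Tuple[str, str], AnalysisCell] = {}
    for outcome in opts.outcomes:
        window = select_window(records, outcome, opts)
        for scen_name in opts.scenarios:
            scenario = ExposureScenario.from_name(scen_name)
            inc, n_excl = apply_scenario(window, scenario)
            spec = ModelSpec(
                outcome=outcome, n_levels=opts.n_levels[outcome],
                fixed_terms=tuple(opts.fixed_terms),
                random_terms=tuple(opts.random_terms),
                quadrature_nodes=opts.quadrature_nodes)
            cell = AnalysisCell(outcome=outcome, scenario=scen_name,
                                n_records=len(inc), excluded=n_excl,
                                interactions=None, strata={})
            fit_kw = dict(restarts=opts.fit_restarts,
                          maxiter=opts.fit_maxiter)
            try:
                if opts.do_interactions:
                    cell.interactions = interaction_analysis(
                        inc, spec, scenario, opts, **fit_kw)
                stratify = (opts.stratify_by_rural == "always"
                            or (opts.stratify_by_rural == "auto"
                                and cell.interactions is not None
                                and cell.interactions.stratify))
                strata = ({"urban": inc[inc["rural"] == 0],
                           "rural": inc[inc["rural"] == 1]}
                          if stratify else {"pooled": inc})
                for sname, sub in strata.items():
                    sr = StratumResult()
                    try:
                        if (sname == "pooled" and cell.interactions is not None
                                and cell.interactions.base_fit is not None):
                            sr.fit = cell.interactions.base_fit
                        else:
                            sspec = _stratum_spec(spec, sname)
                            model = MultilevelPoissonITS.from_records(
                                sub, sspec, scenario)
                            sr.fit = model.fit(**fit_kw)
                        sr.vif = vif(sr.fit.bundle)
                        sr.grid = standardize(sr.fit,
                                              horizons=opts.horizons)
                    except Exception:
                        sr.error = traceback.format_exc(limit=2)
                    cell.strata[sname] = sr
            except Exception:
                cell.error = traceback.format_exc(limit=2)
            cells[(outcome, scen_name)] = cell

    return AnalysisReport(
        config_hash=config.config_hash() if config else "",
        seed=config.seed if config else None, flow=flow,
        characteristics=chars, cells=cells)
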