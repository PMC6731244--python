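"""Deterministic generators: toy pathway databases, omics tables with
planted effects, and two-state feeding traces.

Every generator is a pure function of its arguments (seed included), so
repeated calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flic_events import SAMPLE_RATE_HZ, FlicTrace
from .metabolomics_stats import OmicsTable
from .pathway_db import (
    Compound,
    Enzyme,
    Gene,
    MetabolicDatabase,
    Pathway,
    Reaction,
)

__all__ = [
    "SimulationSpec",
    "PlantedEffect",
    "TraceModel",
    "make_toy_database",
    "simulate_omics_table",
    "simulate_flic_trace",
]


# ---------------------------------------------------------------------------
# toy pathway databases
# ---------------------------------------------------------------------------

def _tca_entities():
    compounds = [
        Compound("C_ACCOA", "acetyl-CoA", synonyms=("acetyl coenzyme A",), xrefs={"KEGG": "C00024"}, class_label="energy"),
        Compound("C_CIT", "citrate", xrefs={"KEGG": "C00158"}, class_label="energy"),
        Compound("C_ACO", "cis-aconitate", synonyms=("aconitate",), xrefs={"KEGG": "C00417"}, class_label="energy"),
        Compound("C_ICIT", "isocitrate", xrefs={"KEGG": "C00311"}, class_label="energy"),
        Compound("C_AKG", "alpha-ketoglutarate", synonyms=("2-oxoglutarate",), xrefs={"KEGG": "C00026"}, class_label="energy"),
        Compound("C_SUC", "succinate", xrefs={"KEGG": "C00042"}, class_label="energy"),
        Compound("C_FUM", "fumarate", xrefs={"KEGG": "C00122"}, class_label="energy"),
        Compound("C_MAL", "malate", synonyms=("L-malate",), xrefs={"KEGG": "C00149"}, class_label="energy"),
        Compound("C_OAA", "oxaloacetate", xrefs={"KEGG": "C00036"}, class_label="energy"),
    ]
    reactions = [
        Reaction("R_CS", ("C_ACCOA", "C_OAA"), ("C_CIT",), False, ("E_CS",), ("PW_TCA",)),
        Reaction("R_ACO1", ("C_CIT",), ("C_ACO",), True, ("E_ACO",), ("PW_TCA",)),
        Reaction("R_ACO2", ("C_ACO",), ("C_ICIT",), True, ("E_ACO",), ("PW_TCA",)),
        Reaction("R_IDH", ("C_ICIT",), ("C_AKG",), False, ("E_IDH",), ("PW_TCA",)),
        Reaction("R_KGDH", ("C_AKG",), ("C_SUC",), False, ("E_KGDH",), ("PW_TCA",)),
        Reaction("R_SDH", ("C_SUC",), ("C_FUM",), True, ("E_SDH",), ("PW_TCA",)),
        Reaction("R_FUM", ("C_FUM",), ("C_MAL",), True, ("E_FUMA",), ("PW_TCA",)),
        Reaction("R_MDH", ("C_MAL",), ("C_OAA",), True, ("E_MDH",), ("PW_TCA",)),
    ]
    enzymes = [
        Enzyme("E_CS", "citrate synthase", ("G_KDN", "G_CS2"), ("R_CS",)),
        Enzyme("E_ACO", "aconitase", ("G_ACON",), ("R_ACO1", "R_ACO2")),
        Enzyme("E_IDH", "isocitrate dehydrogenase", ("G_IDH",), ("R_IDH",)),
        Enzyme("E_KGDH", "alpha-ketoglutarate dehydrogenase", ("G_KGDH",), ("R_KGDH",)),
        Enzyme("E_SDH", "succinate dehydrogenase", ("G_SDHA",), ("R_SDH",)),
        Enzyme("E_FUMA", "fumarase", ("G_FUM",), ("R_FUM",)),
        Enzyme("E_MDH", "malate dehydrogenase", ("G_MDH",), ("R_MDH",)),
    ]
    genes = [
        Gene("G_KDN", "kdn", ("E_CS",)),
        Gene("G_CS2", "CG3861", ("E_CS",)),
        Gene("G_ACON", "Acon", ("E_ACO",)),
        Gene("G_IDH", "Idh", ("E_IDH",)),
        Gene("G_KGDH", "Nc73EF", ("E_KGDH",)),
        Gene("G_SDHA", "SdhA", ("E_SDH",)),
        Gene("G_FUM", "Fum1", ("E_FUMA",)),
        Gene("G_MDH", "Mdh1", ("E_MDH",)),
    ]
    pathway = Pathway(
        "PW_TCA",
        "TCA cycle",
        tuple(c.id for c in compounds),
        tuple(r.id for r in reactions),
    )
    return compounds, reactions, enzymes, genes, pathway


def make_toy_database(variant: str = "tca+glycolysis+bcaa") -> MetabolicDatabase:
    """Hand-curated deterministic toy databases.

    ``tca``: 9 compounds in an 8-reaction cycle.
    ``tca+glycolysis+bcaa``: 18 compounds, 14 reactions, 9 enzymes,
    11 genes, 3 pathways; the BCAA pathway routes leucine/valine/
    isoleucine plus alpha-ketoglutarate through a single transaminase
    reaction whose gene mirrors a branched-chain aminotransferase.
    """
    compounds, reactions, enzymes, genes, tca_pw = _tca_entities()
    if variant == "tca":
        return MetabolicDatabase(
            compounds, reactions, enzymes, genes, [tca_pw], provenance="toy:tca"
        )
    if variant != "tca+glycolysis+bcaa":
        raise ValueError(f"unknown toy-database variant {variant!r}")

    compounds += [
        Compound("C_GLC", "glucose", synonyms=("D-glucose",), xrefs={"KEGG": "C00031"}, class_label="carbohydrate"),
        Compound("C_G6P", "glucose 6-phosphate", xrefs={"KEGG": "C00092"}, class_label="carbohydrate"),
        Compound("C_PEP", "phosphoenolpyruvate", xrefs={"KEGG": "C00074"}, class_label="carbohydrate"),
        Compound("C_PYR", "pyruvate", xrefs={"KEGG": "C00022"}, class_label="carbohydrate"),
        Compound("C_LAC", "lactate", synonyms=("L-lactate",), xrefs={"KEGG": "C00186"}, class_label="carbohydrate"),
        Compound("C_LEU", "leucine", synonyms=("L-leucine",), xrefs={"KEGG": "C00123"}, class_label="amino acid"),
        Compound("C_VAL", "valine", synonyms=("L-valine",), xrefs={"KEGG": "C00183"}, class_label="amino acid"),
        Compound("C_ILE", "isoleucine", synonyms=("L-isoleucine",), xrefs={"KEGG": "C00407"}, class_label="amino acid"),
        Compound("C_KIC", "ketoisocaproate", synonyms=("branched-chain keto acid",), xrefs={"KEGG": "C00233"}, class_label="amino acid"),
    ]
    reactions += [
        Reaction("R_HK", ("C_GLC",), ("C_G6P",), False, ("E_HK",), ("PW_GLY",)),
        Reaction("R_GLY", ("C_G6P",), ("C_PEP",), False, (), ("PW_GLY",)),
        Reaction("R_PK", ("C_PEP",), ("C_PYR",), False, (), ("PW_GLY",)),
        Reaction("R_LDH", ("C_PYR",), ("C_LAC",), True, (), ("PW_GLY",)),
        Reaction("R_PDH", ("C_PYR",), ("C_ACCOA",), False, (), ("PW_GLY",)),
        Reaction(
            "R_BCAT",
            ("C_LEU", "C_VAL", "C_ILE", "C_AKG"),
            ("C_KIC",),
            False,
            ("E_BCAT",),
            ("PW_BCAA",),
        ),
    ]
    enzymes += [
        Enzyme("E_HK", "hexokinase", ("G_HEX",), ("R_HK",)),
        Enzyme("E_BCAT", "branched-chain amino acid transaminase", ("G_BCAT",), ("R_BCAT",)),
    ]
    genes += [
        Gene("G_HEX", "Hex-A", ("E_HK",)),
        Gene("G_BCAT", "CG1673", ("E_BCAT",)),
        Gene("G_ORPHAN", "CG9999", ()),  # isolated gene: allowed by validation
    ]
    pathways = [
        tca_pw,
        Pathway(
            "PW_GLY",
            "glycolysis",
            ("C_GLC", "C_G6P", "C_PEP", "C_PYR", "C_LAC", "C_ACCOA"),
            ("R_HK", "R_GLY", "R_PK", "R_LDH", "R_PDH"),
        ),
        Pathway(
            "PW_BCAA",
            "branched-chain amino acid metabolism",
            ("C_LEU", "C_VAL", "C_ILE", "C_AKG", "C_KIC"),
            ("R_BCAT",),
        ),
    ]
    return MetabolicDatabase(
        compounds, reactions, enzymes, genes, pathways,
        provenance="toy:tca+glycolysis+bcaa",
    )


# ---------------------------------------------------------------------------
# omics table simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative shift of one feature set in one condition."""

    features: tuple[str, ...]
    condition: str
    log2_fold_change: float


@dataclass(frozen=True)
class TraceModel:
    """Two-state feeding-bout model at 5 Hz."""

    bout_rate_per_min: float = 1.0
    mean_bout_samples: float = 12.0
    signal_eating: float = 120.0
    signal_baseline: float = 5.0
    noise_sd: float = 3.0


@dataclass
class SimulationSpec:
    seed: int
    n_features: int = 100
    conditions: tuple[str, ...] = ("A", "B")
    replicates: int = 5
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.0
    cv: float = 0.2
    effects: tuple[PlantedEffect, ...] = ()
    missing_rate: float = 0.0
    missing_excess: Mapping[str, float] = field(default_factory=dict)
    trace: TraceModel = field(default_factory=TraceModel)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        for cond, rate in self.missing_excess.items():
            if cond not in self.conditions:
                raise ValueError(f"missing_excess names unknown condition {cond!r}")
            if not 0 <= rate <= 1:
                raise ValueError("missing_excess rates must be in [0, 1]")
        if self.cv <= 0:
            raise ValueError("cv must be positive")


def simulate_omics_table(spec: SimulationSpec) -> tuple[OmicsTable, pd.DataFrame]:
    """Log-normal abundances with planted fold changes and missingness.

    Returns the table plus a ground-truth frame (feature, condition,
    log2fc) listing the planted effects.  Missingness combines uniform
    dropout at ``missing_rate`` with per-condition left-censoring below
    the condition's ``missing_excess`` detection quantile.
    """
    rng = np.random.default_rng(spec.seed)
    features = [f"F{i:04d}" for i in range(spec.n_features)]
    samples: list[str] = []
    condition_of: dict[str, str] = {}
    for cond in spec.conditions:
        for r in range(spec.replicates):
            sid = f"{cond}_{r + 1}"
            samples.append(sid)
            condition_of[sid] = cond

    base_log = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_features)
    sigma = np.sqrt(np.log1p(spec.cv**2))  # log-normal sd giving the requested CV

    effect_l2fc = pd.DataFrame(0.0, index=features, columns=list(spec.conditions))
    truth_rows = []
    for eff in spec.effects:
        unknown = set(eff.features) - set(features)
        if unknown:
            raise ValueError(f"effects: unknown feature(s) {sorted(unknown)[:5]}")
        if eff.condition not in spec.conditions:
            raise ValueError(f"effects: unknown condition {eff.condition!r}")
        for f in eff.features:
            effect_l2fc.loc[f, eff.condition] += eff.log2_fold_change
            truth_rows.append((f, eff.condition, eff.log2_fold_change))
    truth = pd.DataFrame(truth_rows, columns=["feature", "condition", "log2fc"])

    matrix = np.empty((spec.n_features, len(samples)))
    for j, sid in enumerate(samples):
        cond = condition_of[sid]
        mu = base_log + effect_l2fc[cond].to_numpy() * np.log(2.0)
        matrix[:, j] = np.exp(rng.normal(mu, sigma))

    values = pd.DataFrame(matrix, index=features, columns=samples)

    if spec.missing_rate > 0 or spec.missing_excess:
        mask = rng.random(values.shape) < spec.missing_rate
        for cond, rate in spec.missing_excess.items():
            if rate <= 0:
                continue
            cols = [j for j, sid in enumerate(samples) if condition_of[sid] == cond]
            block = matrix[:, cols]
            cutoff = np.quantile(block, rate)
            censored = block < cutoff  # left-censoring below detection limit
            for bj, j in enumerate(cols):
                mask[:, j] |= censored[:, bj]
        values = values.mask(mask)

    table = OmicsTable(
        values=values,
        conditions=pd.Series(condition_of, name="condition").reindex(samples),
        scale="raw",
    )
    return table, truth


# ---------------------------------------------------------------------------
# FLIC trace simulation
# ---------------------------------------------------------------------------


def simulate_flic_trace(
    spec: SimulationSpec,
    n_flies: int = 1,
    duration_s: float = 3600.0,
    device_ids: Sequence[str] | None = None,
) -> tuple[list[FlicTrace], list[list[tuple[int, int]]]]:
    """Two-state renewal process at 5 Hz with known bout ground truth.

    Returns traces plus, per fly, the list of true (start, end)
    inclusive sample intervals of the generated bouts.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.trace
    n_samples = int(round(duration_s * SAMPLE_RATE_HZ))
    p_start = model.bout_rate_per_min / 60.0 / SAMPLE_RATE_HZ
    p_stop = 1.0 / model.mean_bout_samples if model.mean_bout_samples > 0 else 1.0

    traces: list[FlicTrace] = []
    truths: list[list[tuple[int, int]]] = []
    for fly in range(n_flies):
        device = device_ids[fly % len(device_ids)] if device_ids else f"D{fly % 4 + 1}"
        eating = np.zeros(n_samples, dtype=bool)
        state = False
        start = 0
        bouts: list[tuple[int, int]] = []
        for i in range(n_samples):
            if state:
                if rng.random() < p_stop:
                    # bout ends; sample i is forced non-eating so adjacent
                    # bouts are always separated by >= 1 gap sample
                    bouts.append((start, i - 1))
                    state = False
                else:
                    eating[i] = True
            elif rng.random() < p_start:
                state = True
                start = i
                eating[i] = True
        if state:
            bouts.append((start, n_samples - 1))
        signal = np.where(eating, model.signal_eating, model.signal_baseline)
        signal = signal + rng.normal(0.0, model.noise_sd, n_samples)
        traces.append(FlicTrace(fly_id=f"fly{fly + 1}", device_id=device, signal=signal))
        truths.append(bouts)
    return traces, truths
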