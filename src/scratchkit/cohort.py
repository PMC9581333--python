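"""Synthetic per-animal cohort tables with the study's strain x dose design.

Each pruritogen group is a fixed set of animals, and every animal is tested
at all four dose-folds on separate days (repeated-measures layout, 48 h
apart: the 3-fold dose on day 1, 1-fold on day 3, 10-fold on day 5 and the
0.3-fold dose last, on day 8).  Bout counts are drawn per animal x dose from
a count model matched to the group's mean and dispersion; the anchor table
shipped in ``data/group_means.yaml`` parameterizes the default cells.

Scratch time and event counts are derived from the bout count through a
shared multiplicative driver (per-bout duration, bouts per event), which is
what makes the three session metrics strongly correlated across animals, as
they are in real recordings.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSpec",
    "load_group_means",
    "default_cohort_spec",
    "simulate_cohort",
    "draw_counts",
    "DOSE_DAY",
]

#: injection sequence: dose-fold -> test day
DOSE_DAY = {3.0: 1, 1.0: 3, 10.0: 5, 0.3: 8}

MeanTable = dict[str, dict[str, dict]]  # strain -> pruritogen -> {n, doses}


def load_group_means() -> dict:
    """Parsed default anchor table (see data/group_means.yaml for provenance)."""
    ref = importlib.resources.files("scratchkit.data").joinpath("group_means.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class CohortSpec:
    """Design and distributional parameters of a simulated cohort.

    ``group_mean_table`` follows the YAML schema: strain -> pruritogen ->
    {n, doses: {dose_fold: {mean, sem, source}}}.  Per-animal SD of a cell is
    ``sem * sqrt(n)`` with the table's n (the published group size), so the
    simulated animals reproduce the published group dispersion regardless of
    ``n_per_group``.
    """

    strains: tuple[str, ...] = ("C57", "C3H")
    pruritogens: tuple[str, ...] = (
        "endothelin", "chloroquine", "trypsin", "LPA", "histamine", "5-HT", "SLIGRL",
    )
    dose_folds: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0)
    n_per_group: int = 8
    group_mean_table: MeanTable = field(default_factory=lambda: load_group_means()["strains"])
    sex_ratio: float = 0.5
    count_model: str = "negative_binomial"  # or "lognormal_rounded"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("degenerate group: n_per_group must be >= 2")
        if list(self.dose_folds) != sorted(self.dose_folds):
            raise ValueError("dose_folds must be sorted ascending")
        if self.count_model not in ("negative_binomial", "lognormal_rounded"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for strain in self.strains:
            for prur in self.pruritogens:
                cell = self.group_mean_table[strain][prur]
                for d in self.dose_folds:
                    spec = cell["doses"][_dose_key(cell["doses"], d)]
                    if spec["mean"] < 0:
                        raise ValueError("means must be nonnegative")
                    if spec["sem"] <= 0:
                        raise ValueError("dispersions must be positive")


def _dose_key(doses: dict, dose: float):
    for k in doses:
        if float(k) == float(dose):
            return k
    raise KeyError(f"dose fold {dose} not in table")


def draw_counts(
    rng: np.random.Generator, mean: float, sd: float, size: int, model: str = "negative_binomial"
) -> np.ndarray:
    """Nonnegative integer counts with the requested first two moments.

    Negative binomial requires variance > mean; at or below that limit (and
    always under ``lognormal_rounded``) a moment-matched lognormal is
    rounded instead, which degenerates to ``round(mean)`` as sd -> 0.
    """
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be nonnegative")
    if sd == 0 or mean == 0:
        return np.full(size, int(round(mean)))
    var = sd**2
    if model == "negative_binomial" and var > mean:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.round(rng.lognormal(mu, np.sqrt(sigma2), size=size)).astype(int)


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """One row per animal x dose with columns
    ``animal_id,strain,sex,pruritogen,dose_fold,day,bouts,events,scratch_time_s``.

    Deterministic for identical (spec, seed).
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for strain in spec.strains:
        for prur in spec.pruritogens:
            cell = spec.group_mean_table[strain][prur]
            n_ref = cell["n"]
            n_female = int(round(spec.sex_ratio * spec.n_per_group))
            sexes = ["f"] * n_female + ["m"] * (spec.n_per_group - n_female)
            animal_ids = [f"{strain}-{prur}-{i + 1:02d}" for i in range(spec.n_per_group)]
            # animal-level drivers shared across doses
            bout_dur = rng.lognormal(np.log(0.6), 0.15, size=spec.n_per_group)
            bouts_per_event = rng.uniform(2.5, 3.5, size=spec.n_per_group)
            for dose in spec.dose_folds:
                dspec = cell["doses"][_dose_key(cell["doses"], dose)]
                sd = dspec["sem"] * np.sqrt(n_ref)
                counts = draw_counts(rng, dspec["mean"], sd, spec.n_per_group, spec.count_model)
                times = np.minimum(counts * bout_dur, 1800.0)
                events = np.where(counts > 0, np.maximum(1, np.round(counts / bouts_per_event)), 0)
                for a in range(spec.n_per_group):
                    rows.append(
                        {
                            "animal_id": animal_ids[a],
                            "strain": strain,
                            "sex": sexes[a],
                            "pruritogen": prur,
                            "dose_fold": float(dose),
                            "day": DOSE_DAY.get(float(dose), 0),
                            "bouts": int(counts[a]),
                            "events": int(events[a]),
                            "scratch_time_s": float(times[a]),
                        }
                    )
    return pd.DataFrame(rows)


def default_cohort_spec(**overrides) -> CohortSpec:
    return CohortSpec(**overrides)
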