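"""Run configuration: every tunable of the pipeline in one round-trippable file.

The YAML representation is the interchange form; ``config_hash`` of the
canonical dump is stamped into every output table so results are traceable.
Each default is tagged with its provenance: ``study`` for values fixed by
the study's protocol (band, CV rule, fences, window) and ``chosen`` for
artifact-level choices (sampling rate, event-gap threshold, match
tolerance).
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .detect import DetectorParams
from .simulate import ConfounderSpec, SignalParams

__all__ = ["RunConfig", "config_hash"]

#: provenance of the defaults, keyed by dotted field name
PROVENANCE = {
    "detector.band": "study",
    "detector.cv_max": "study",
    "detector.analysis_window_s": "study",
    "detector.min_beats_per_bout": "chosen",
    "detector.event_gap_s": "chosen",
    "detector.amp_threshold_k": "chosen",
    "signal.sampling_rate": "chosen",
    "signal.beat_freq_range": "study",
    "stats.alpha": "study",
    "stats.outlier_k": "study",
    "stats.normality_method": "chosen",
    "stats.quantile_method": "chosen",
    "validation.match_tolerance_s": "chosen",
    "validation.match_unit": "chosen (bout-level)",
}


@dataclass
class StatsOptions:
    alpha: float = 0.05
    normality_method: str = "shapiro_wilk"
    quantile_method: str = "linear"
    outlier_k: float = 2.2
    by_sex: bool = False


@dataclass
class RunConfig:
    signal: SignalParams = field(default_factory=SignalParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    stats: StatsOptions = field(default_factory=StatsOptions)
    match_tolerance_s: float = 0.5
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        try:
            is_file = Path(str(source)).is_file()
        except (OSError, ValueError):
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        doc = yaml.safe_load(text)
        sig = dict(doc.get("signal", {}))
        if "confounder_spec" in sig:
            sig["confounder_spec"] = tuple(
                ConfounderSpec(**{k: _tup(v) if k.endswith("range") else v for k, v in c.items()})
                for c in sig["confounder_spec"]
            )
        for key in ("beat_freq_range", "beats_per_bout_range",
                    "bouts_per_event_range", "intra_event_gap_s"):
            if key in sig:
                sig[key] = _tup(sig[key])
        det = dict(doc.get("detector", {}))
        if "band" in det:
            det["band"] = _tup(det["band"])
        coh = dict(doc.get("cohort", {}))
        for key in ("strains", "pruritogens", "dose_folds"):
            if key in coh:
                coh[key] = _tup(coh[key])
        return cls(
            signal=SignalParams(**sig),
            detector=DetectorParams(**det),
            cohort=CohortSpec(**coh),
            stats=StatsOptions(**doc.get("stats", {})),
            match_tolerance_s=doc.get("match_tolerance_s", 0.5),
            seed=doc.get("seed", 0),
            out_dir=doc.get("out_dir", "."),
        )

    @property
    def hash(self) -> str:
        return config_hash(self)


def _tup(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


def _plain(obj):
    """Recursively coerce tuples to lists for stable YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]
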