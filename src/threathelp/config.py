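"""Pipeline configuration: one YAML file drives every stage.

The file has nested sections mirroring the parameter dataclasses
(``design``, ``ratings``, ``neural``, ``decisions``, ``analysis``) plus the
cohort size, the master seed and a log level.  The loaded config is echoed
into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import DEFAULT_ROI_LIST, TaskDesign
from .exceptions import ValidationError
from .simulate import DecisionParams, NeuralParams, RatingParams


@dataclass
class AnalysisParams:
    """Knobs of the similarity analysis itself."""

    roi_list: tuple[str, ...] = DEFAULT_ROI_LIST
    variant: str = "tau_a"
    alpha: float = 0.05
    fdr_pool: str = "slopes"
    cluster_robust: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not self.roi_list:
            raise ValidationError("roi_list must be non-empty")
        if self.variant not in ("tau_a", "tau_b"):
            raise ValidationError(f"unknown tau variant {self.variant!r}")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    output_dir: str = "threathelp_out"
    n_subjects: int = 49
    seed: int = 0
    log_level: str = "INFO"
    design: TaskDesign = field(default_factory=TaskDesign)
    ratings: RatingParams = field(default_factory=RatingParams)
    neural: NeuralParams = field(default_factory=NeuralParams)
    decisions: DecisionParams = field(default_factory=DecisionParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("a master seed is required")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        self.analysis.validate()
        self.neural.validate()
        self.decisions.validate()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            d = dataclasses.asdict(obj)
            return {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
            }

        return {
            "output_dir": self.output_dir,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "log_level": self.log_level,
            "design": enc(self.design),
            "ratings": enc(self.ratings),
            "neural": enc(self.neural),
            "decisions": enc(self.decisions),
            "analysis": enc(self.analysis),
        }

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, section, tuple_fields=()):
            data = dict(raw.get(section) or {})
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - known
            if unknown:
                raise ValidationError(
                    f"unknown keys in config section {section!r}: {sorted(unknown)}"
                )
            for tf in tuple_fields:
                if tf in data and isinstance(data[tf], list):
                    data[tf] = tuple(data[tf])
            return klass(**data)

        known_top = {"output_dir", "n_subjects", "seed", "log_level"}
        sections = {"design", "ratings", "neural", "decisions", "analysis"}
        unknown = set(raw) - known_top - sections
        if unknown:
            raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
        cfg = cls(
            output_dir=raw.get("output_dir", "threathelp_out"),
            n_subjects=raw.get("n_subjects", 49),
            seed=raw.get("seed", 0),
            log_level=raw.get("log_level", "INFO"),
            design=build(TaskDesign, "design", tuple_fields=("levels",)),
            ratings=build(RatingParams, "ratings"),
            neural=build(NeuralParams, "neural", tuple_fields=("rois",)),
            decisions=build(DecisionParams, "decisions"),
            analysis=build(AnalysisParams, "analysis", tuple_fields=("roi_list",)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)
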