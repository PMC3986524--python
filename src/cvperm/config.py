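"""Parse and validate the JSON inference descriptor.

A run is driven entirely by a declarative JSON document with sections for
general parameters (covariates, number of permutations B, permutations per
map task), the prediction score (metric and outer shuffle-split scheme),
the estimator pipeline, and an optional hyper-parameter grid searched by an
inner 5-fold cross-validation.  Unknown keys are hard errors: a silent typo
in a descriptor that drives weeks of computation is unacceptable.

Components are addressed either by a built-in registry key
(``collinearity_filter``, ``select_k_best``, ``ridge``) or by a
``DYNAMIC_IMPORT::module.path.Object`` plugin reference, resolved lazily at
worker start so the controller never needs the plugin installed.
"""

from __future__ import annotations

import importlib
import json
import math
from typing import Any, Literal, Mapping

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from .exceptions import ConfigError, PluginError

__all__ = [
    "DYNAMIC_IMPORT_PREFIX",
    "CVScheme",
    "EstimatorStep",
    "GridSpec",
    "InferenceDescriptor",
    "parse_descriptor",
    "load_descriptor",
    "resolve_component",
]

DYNAMIC_IMPORT_PREFIX = "DYNAMIC_IMPORT::"

#: Fixed fold count of the inner model-selection loop.
INNER_CV_FOLDS = 5


class CVScheme(BaseModel):
    """Outer shuffle-split scheme: n_iter random train/test subsamplings."""

    model_config = ConfigDict(extra="forbid")

    n_iter: int = Field(default=10, ge=1)
    test_fraction: float = Field(default=0.2, gt=0.0, lt=1.0)
    seed: int = 0


class EstimatorStep(BaseModel):
    """One pipeline step: a name, a component reference, and its parameters."""

    model_config = ConfigDict(extra="forbid")

    name: str
    component_ref: str
    parameters: dict[str, Any] = Field(default_factory=dict)

    @field_validator("name")
    @classmethod
    def _name_is_identifier(cls, v: str) -> str:
        if not v.isidentifier():
            raise ValueError(f"step name {v!r} is not a valid identifier")
        return v


class GridSpec(BaseModel):
    """Hyper-parameter axes, searched exhaustively by the inner CV loop."""

    model_config = ConfigDict(extra="forbid")

    axes: dict[str, list[Any]]
    inner_cv_folds: Literal[5] = INNER_CV_FOLDS

    @field_validator("axes")
    @classmethod
    def _axes_nonempty(cls, v: dict[str, list[Any]]) -> dict[str, list[Any]]:
        if not v:
            raise ValueError("grid must have at least one axis")
        for key, values in v.items():
            if "__" not in key:
                raise ValueError(
                    f"grid key {key!r} must have the form '<step>__<parameter>'"
                )
            if not values:
                raise ValueError(f"grid axis {key!r} has no candidate values")
        return v

    @property
    def n_candidates(self) -> int:
        """Total number of grid points (product of axis lengths)."""
        return math.prod(len(v) for v in self.axes.values())


class InferenceDescriptor(BaseModel):
    """Validated, fully-defaulted form of the JSON inference descriptor."""

    model_config = ConfigDict(extra="forbid")

    with_covariates: bool
    n_permutations: int = Field(ge=1)
    permutations_per_task: int = Field(default=1, ge=1)
    score: Literal["r2"] = "r2"
    cv: CVScheme = Field(default_factory=CVScheme)
    pipeline: list[EstimatorStep]
    grid: GridSpec | None = None
    covariate_mode: Literal["full_sample", "per_fold"] = "full_sample"

    @model_validator(mode="after")
    def _check_consistency(self) -> "InferenceDescriptor":
        if self.n_permutations % self.permutations_per_task != 0:
            raise ValueError(
                f"n_permutations={self.n_permutations} is not divisible by "
                f"permutations_per_task={self.permutations_per_task}"
            )
        if not self.pipeline:
            raise ValueError("pipeline must have at least one step")
        names = [s.name for s in self.pipeline]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate step names in pipeline: {names}")
        # transformer/predictor roles are checkable for built-ins only;
        # plugins are validated when resolved at worker start
        from . import estimator as _est

        for i, step in enumerate(self.pipeline):
            ref = step.component_ref
            if ref.startswith(DYNAMIC_IMPORT_PREFIX):
                continue
            if ref not in _est.REGISTRY:
                raise ValueError(
                    f"unknown component {ref!r} in pipeline step {step.name!r}"
                )
            cls = _est.REGISTRY[ref]
            last = i == len(self.pipeline) - 1
            if last and not hasattr(cls, "predict"):
                raise ValueError(
                    f"last pipeline step {step.name!r} ({ref}) is not a predictor"
                )
            if not last and not hasattr(cls, "transform"):
                raise ValueError(
                    f"pipeline step {step.name!r} ({ref}) is not a transformer"
                )
        if self.grid is not None:
            for key in self.grid.axes:
                step_name = key.partition("__")[0]
                if step_name not in names:
                    raise ValueError(
                        f"grid key {key!r} references step {step_name!r} "
                        f"absent from the pipeline (steps: {names})"
                    )
        return self

    # -- convenience aliases matching the run-time vocabulary ---------------
    @property
    def B(self) -> int:
        """Number of permutations."""
        return self.n_permutations

    def to_json(self, **kwargs: Any) -> str:
        """Serialize back to the JSON descriptor dialect."""
        return self.model_dump_json(exclude_none=True, **kwargs)


def parse_descriptor(raw_text: str) -> InferenceDescriptor:
    """Parse and validate a JSON inference descriptor.

    Raises
    ------
    ConfigError
        On malformed JSON (naming the position) or on any schema violation
        (naming the offending key).
    """
    try:
        doc = json.loads(raw_text)
    except json.JSONDecodeError as exc:
        raise ConfigError(
            f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(doc, dict):
        raise ConfigError("descriptor must be a JSON object")
    try:
        return InferenceDescriptor.model_validate(doc)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in exc.errors()
        )
        raise ConfigError(f"invalid descriptor: {issues}") from exc


def load_descriptor(path: str) -> InferenceDescriptor:
    """Read and parse a descriptor file (UTF-8 JSON)."""
    with open(path, encoding="utf-8") as fh:
        return parse_descriptor(fh.read())


def resolve_component(ref: str, registry: Mapping[str, type] | None = None) -> type:
    """Resolve a component reference to an instantiable class.

    ``ref`` is either a key of ``registry`` (default: the built-in registry)
    or ``DYNAMIC_IMPORT::dotted.module.Attribute`` (``:`` also accepted as
    the module/attribute separator).
    """
    from . import estimator as _est

    if registry is None:
        registry = _est.REGISTRY
    if ref.startswith(DYNAMIC_IMPORT_PREFIX):
        target = ref[len(DYNAMIC_IMPORT_PREFIX):]
        if ":" in target:
            mod_name, _, attr_path = target.partition(":")
        else:
            mod_name, _, attr_path = target.rpartition(".")
        if not mod_name or not attr_path:
            raise PluginError(f"cannot parse plugin reference {ref!r}")
        try:
            obj: Any = importlib.import_module(mod_name)
        except ImportError as exc:
            raise PluginError(f"cannot import module for {ref!r}: {exc}") from exc
        try:
            for part in attr_path.split("."):
                obj = getattr(obj, part)
        except AttributeError as exc:
            raise PluginError(f"cannot resolve attribute for {ref!r}: {exc}") from exc
        return obj
    try:
        return registry[ref]
    except KeyError:
        raise ConfigError(
            f"unknown component {ref!r}; built-ins: {sorted(registry)}"
        ) from None
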