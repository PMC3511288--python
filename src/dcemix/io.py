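"""Readers, writers and the end-to-end pipeline.

Choice data travel as long-format CSV (one row per respondent x task x
alternative) plus a covariate CSV and a JSON provenance sidecar; designs and
results as JSON.  ``run_pipeline`` chains design -> simulate -> validate ->
fit -> report with a single seed, embedding the configuration hash in every
output so re-runs with a changed configuration never overwrite silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ChoiceDesign
from .estimation import MixedLogitSpec, fit
from .exceptions import ConfigurationError, DataValidationError
from .postestimation import (
    classify_harm_benefit,
    conditional_individual_coefficients,
    fit_statistics,
    hit_rate,
    relative_importance,
)
from .simulate import (
    ChoiceDataset,
    PRESET_GROUPING,
    simulate_dataset,
    study_emulation_preset,
)
from .validity import validity_report

logger = logging.getLogger("dcemix")

REQUIRED_COLUMNS = ("respondent", "task", "alternative", "chosen")


def validate_choice_frame(df: pd.DataFrame) -> None:
    """Enforce the long-format contract with row-level error messages."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DataValidationError(f"missing required column {col!r}")
    attr_cols = [c for c in df.columns if c not in ChoiceDataset.ID_COLUMNS]
    for col in attr_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise DataValidationError(f"attribute column {col!r} is not numeric")
    if not set(df["alternative"].unique()) <= {"A", "B"}:
        raise DataValidationError("alternative labels must be 'A' or 'B'")
    counts = df.groupby(["respondent", "task"])["chosen"].sum()
    bad = counts[counts != 1]
    if len(bad):
        r, t = bad.index[0]
        raise DataValidationError(
            f"respondent {r!r} task {t!r} has {int(bad.iloc[0])} chosen flags "
            "(exactly 1 required)"
        )
    sizes = df.groupby(["respondent", "task"]).size()
    bad = sizes[sizes != 2]
    if len(bad):
        r, t = bad.index[0]
        raise DataValidationError(
            f"respondent {r!r} task {t!r} has {int(bad.iloc[0])} rows (2 required)"
        )


def write_choice_data(data: ChoiceDataset, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "choices": directory / "choices.csv",
        "covariates": directory / "covariates.csv",
        "provenance": directory / "provenance.json",
    }
    data.choices.to_csv(paths["choices"], index=False)
    data.covariates.to_csv(paths["covariates"])
    paths["provenance"].write_text(json.dumps(data.provenance, indent=2, sort_keys=True))
    return paths


def read_choice_data(
    path: str | Path, covariates_path: str | Path | None = None
) -> ChoiceDataset:
    """Read a long-format choice CSV (or a directory written by
    :func:`write_choice_data`) into a validated :class:`ChoiceDataset`."""
    path = Path(path)
    if path.is_dir():
        choices_path = path / "choices.csv"
        covariates_path = covariates_path or (path / "covariates.csv")
        prov_path = path / "provenance.json"
    else:
        choices_path, prov_path = path, None
    df = pd.read_csv(choices_path)
    validate_choice_frame(df)
    if covariates_path is not None and Path(covariates_path).exists():
        cov = pd.read_csv(covariates_path, index_col=0)
        cov.index.name = "respondent"
    else:
        cov = pd.DataFrame(index=pd.Index(df["respondent"].unique(), name="respondent"))
    provenance = {}
    if prov_path is not None and prov_path.exists():
        provenance = json.loads(prov_path.read_text())
    return ChoiceDataset(choices=df, covariates=cov, provenance=provenance)


def write_design(design: ChoiceDesign, path: str | Path) -> None:
    Path(path).write_text(json.dumps(design.to_dict(), indent=2, sort_keys=True))


def read_design(path: str | Path) -> ChoiceDesign:
    return ChoiceDesign.from_dict(json.loads(Path(path).read_text()))


def design_to_csv(design: ChoiceDesign, path: str | Path) -> None:
    """Flat export for survey tooling: one row per task x alternative."""
    rows = []
    for t in design.tasks:
        for j, alt in enumerate(t.alternatives):
            rows.append(
                {
                    "task": t.task_id,
                    "block": t.block,
                    "role": t.role,
                    "alternative": "A" if j == 0 else "B",
                    **alt,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run settings.

    Either give ``data_path`` (ingest an observed dataset; requires
    ``design_path``) or leave both unset to simulate from the study
    emulation preset.  The seed drives every stochastic stage.
    """

    seed: int
    out_dir: str
    design_path: str | None = None
    data_path: str | None = None
    n_respondents: int = 161
    n_draws: int = 1000
    draw_type: str = "halton"
    mixing: dict = field(default_factory=dict)
    overwrite: bool = False

    def config_hash(self) -> str:
        """Hash of the scientific settings only — where the artifacts land
        (and whether they may be replaced) does not change their content."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("overwrite", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate(self) -> None:
        if self.data_path is not None and self.design_path is None:
            raise ConfigurationError(
                "data_path given without design_path: validity checks need the design"
            )
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


def _write_json(path: Path, payload: dict, config_hash: str, seed: int, overwrite: bool):
    payload = {"config_hash": config_hash, "seed": seed, **payload}
    if path.exists() and not overwrite:
        existing = json.loads(path.read_text())
        if existing.get("config_hash") != config_hash:
            raise ConfigurationError(
                f"{path} exists with a different config hash; "
                "pass overwrite=True to replace it"
            )
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))


def run_pipeline(config: RunConfig) -> dict:
    """design -> simulate (or ingest) -> validate -> fit -> report.

    Idempotent under an identical configuration and seed; every artifact
    embeds the configuration hash.  Any stage failure is re-raised with the
    stage name prefixed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    bundle: dict = {}
    stage = "setup"
    try:
        stage = "design"
        pop, preset_design = study_emulation_preset(n_respondents=config.n_respondents)
        if config.design_path:
            design = read_design(config.design_path)
        else:
            design = preset_design
        write_design(design, out / "design.json")
        logger.info("design: %d tasks in %d blocks", len(design.tasks), design.n_blocks)

        stage = "simulate"
        if config.data_path:
            data = read_choice_data(config.data_path)
        else:
            data = simulate_dataset(pop, design, seed=config.seed)
        write_choice_data(data, out / "data")
        logger.info("data: %d respondents", data.n_respondents)

        stage = "validate"
        report = validity_report(data, design)
        _write_json(out / "validity.json", report.to_dict(), chash, config.seed,
                    config.overwrite)

        stage = "fit"
        spec = MixedLogitSpec(
            attributes=tuple(design.factor_names),
            mixing=config.mixing or {
                name: m.kind for name, m in pop.coefficients.items()
                if m.kind != "fixed"
            },
            interactions=tuple((a, c) for a, c, _ in pop.interactions),
            n_draws=config.n_draws,
            draw_type=config.draw_type,
            seed=config.seed,
        )
        result = fit(spec, data)
        _write_json(out / "result.json", result.to_dict(), chash, config.seed,
                    config.overwrite)
        logger.info("fit: LL=%.2f converged=%s", result.loglik, result.converged)

        stage = "report"
        stats = fit_statistics(result, data)
        importance = relative_importance(result, design, "individual", data)
        table3 = classify_harm_benefit(importance.individual, PRESET_GROUPING)
        cond = conditional_individual_coefficients(result, data)
        report_payload = {
            "fit_statistics": stats.to_dict(),
            "hit_rate": hit_rate(result, data),
            "relative_importance": importance.to_dict(),
            "harm_benefit": table3.to_dict(orient="records"),
            "conditional_coefficient_means": cond.mean().to_dict(),
        }
        _write_json(out / "report.json", report_payload, chash, config.seed,
                    config.overwrite)
    except Exception as exc:
        raise type(exc)(f"[pipeline stage: {stage}] {exc}") from exc

    bundle.update(
        design=design, data=data, validity=report, result=result,
        fit_statistics=stats, importance=importance, harm_benefit=table3,
        report=report_payload,
    )
    return bundle
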