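"""Plain-text steering files controlling a simulation study.

Dialect: ``key = value`` lines inside ``[section]`` headers; ``#`` or
``;`` start a comment; blank lines ignored.  Sections:

* ``[study]`` — run sizes, seed, methods, prediction doses.
* ``[groups]`` — dose-group bounds, central doses (Gy), person-years,
  individuals per group.
* ``[risk <name>]`` — one dose-response model (``form``, ``alpha``,
  ``beta``); repeatable.
* ``[scenario <name>]`` — one error configuration; repeatable.  The four
  magnitudes (``berkson_shared``, ``berkson_unshared``,
  ``classical_shared``, ``classical_unshared``) accept percentages
  (``50%``) or proportions (``0.5``).
* ``[bma]`` — MCMC settings for the quasi-2DMC BMA sampler.

Anything unset falls back to the package defaults; unknown sections or
keys are rejected with the offending line number.
"""

from __future__ import annotations

from dataclasses import fields as dataclass_fields
from pathlib import Path

from .cohort_sim import RiskModelSpec
from .error_model import DoseGroupSpec, ErrorConfig, default_groups
from .model_averaging import BmaSettings
from .study import ALL_METHODS, StudyConfig

__all__ = ["read_steering", "write_steering", "SteeringError"]


class SteeringError(ValueError):
    """Malformed steering file; message names the line and key."""


_STUDY_KEYS = {"n_meta": int, "m_sub": int, "n_cases": int, "master_seed": int,
               "fma_k": int, "pred_doses": "float_list", "methods": "str_list"}
_GROUP_KEYS = {"bounds": "str_list", "central_doses": "float_list",
               "person_years": "float_list", "n_individuals": "int_list"}
_RISK_KEYS = {"form": str, "alpha": float, "beta": float}
_SCENARIO_KEYS = {"berkson_shared": "sigma", "berkson_unshared": "sigma",
                  "classical_shared": "sigma", "classical_unshared": "sigma"}
_BMA_KEYS = {"prior_sd": float, "proposal_sd_kappa": float,
             "proposal_sd_alpha_beta": float, "proposal_sd_lambda": float,
             "lambda_block": int, "n_chains": int, "burn_in": int,
             "n_keep": int, "bgr_threshold": float}


def _parse_sigma(text: str, lineno: int, key: str) -> float:
    t = text.strip()
    try:
        if t.endswith("%"):
            return float(t[:-1]) / 100.0
        return float(t)
    except ValueError:
        raise SteeringError(f"line {lineno}: cannot parse {key} = {text!r}") from None


def _convert(value: str, kind, lineno: int, key: str):
    try:
        if kind is int:
            return int(value)
        if kind is float:
            return float(value)
        if kind is str:
            return value.strip()
        if kind == "float_list":
            return tuple(float(x) for x in value.split(","))
        if kind == "int_list":
            return tuple(int(x) for x in value.split(","))
        if kind == "str_list":
            return tuple(x.strip() for x in value.split(",") if x.strip())
        if kind == "sigma":
            return _parse_sigma(value, lineno, key)
    except (ValueError, TypeError):
        raise SteeringError(f"line {lineno}: cannot parse {key} = {value!r}") from None
    raise AssertionError(kind)


def read_steering(path) -> StudyConfig:
    """Parse a steering file into a StudyConfig (defaults fill gaps)."""
    text = Path(path).read_text()
    section: str | None = None
    section_name = ""
    study: dict = {}
    groups: dict = {}
    risks: list[tuple[str, dict]] = []
    scenarios: list[tuple[str, dict]] = []
    bma: dict = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise SteeringError(f"line {lineno}: unterminated section header")
            header = line[1:-1].strip()
            parts = header.split(None, 1)
            section = parts[0].lower()
            section_name = parts[1] if len(parts) > 1 else ""
            if section not in ("study", "groups", "risk", "scenario", "bma"):
                raise SteeringError(f"line {lineno}: unknown section [{header}]")
            if section == "risk":
                risks.append((section_name or f"risk{len(risks) + 1}", {}))
            if section == "scenario":
                scenarios.append((section_name or f"scenario{len(scenarios) + 1}", {}))
            continue
        if "=" not in line:
            raise SteeringError(f"line {lineno}: expected 'key = value', got {raw!r}")
        if section is None:
            raise SteeringError(f"line {lineno}: key outside any [section]")
        key, value = (s.strip() for s in line.split("=", 1))
        key = key.lower()
        table = {"study": _STUDY_KEYS, "groups": _GROUP_KEYS, "risk": _RISK_KEYS,
                 "scenario": _SCENARIO_KEYS, "bma": _BMA_KEYS}[section]
        if key not in table:
            raise SteeringError(f"line {lineno}: unknown key {key!r} in [{section}]")
        parsed = _convert(value, table[key], lineno, key)
        if section == "study":
            study[key] = parsed
        elif section == "groups":
            groups[key] = parsed
        elif section == "risk":
            risks[-1][1][key] = parsed
        elif section == "scenario":
            scenarios[-1][1][key] = parsed
        else:
            bma[key] = parsed

    kwargs: dict = dict(study)
    if "methods" in kwargs:
        unknown = set(kwargs["methods"]) - set(ALL_METHODS)
        if unknown:
            raise SteeringError(f"unknown methods {sorted(unknown)}")
    if groups:
        base = default_groups()
        kwargs["groups"] = DoseGroupSpec(
            group_bounds=groups.get("bounds", base.group_bounds),
            central_doses=groups.get("central_doses", base.central_doses),
            person_years=groups.get("person_years", base.person_years),
            n_individuals=groups.get("n_individuals", base.n_individuals),
        )
    if risks:
        kwargs["risk_models"] = tuple(
            RiskModelSpec(alpha=spec.get("alpha", 0.0), beta=spec.get("beta", 0.0),
                          form=spec.get("form", "linear-quadratic"))
            for _, spec in risks
        )
    if scenarios:
        kwargs["scenarios"] = tuple(
            ErrorConfig(
                sigma_share_berkson=spec.get("berkson_shared", 0.0),
                sigma_unshare_berkson=spec.get("berkson_unshared", 0.0),
                sigma_share_class=spec.get("classical_shared", 0.0),
                sigma_unshare_class=spec.get("classical_unshared", 0.0),
            )
            for _, spec in scenarios
        )
    if bma:
        kwargs["bma_settings"] = BmaSettings(**bma)
    return StudyConfig(**kwargs)


def write_steering(config: StudyConfig, path) -> None:
    """Write a StudyConfig as a steering file (read_steering round-trips)."""
    lines = ["[study]"]
    lines.append(f"n_meta = {config.n_meta}")
    lines.append(f"m_sub = {config.m_sub}")
    lines.append(f"n_cases = {config.n_cases}")
    lines.append(f"master_seed = {config.master_seed}")
    lines.append(f"fma_k = {config.fma_k}")
    lines.append("pred_doses = " + ", ".join(repr(d) for d in config.pred_doses))
    lines.append("methods = " + ", ".join(config.methods))
    g = config.groups
    lines += ["", "[groups]",
              "bounds = " + ", ".join(g.group_bounds),
              "central_doses = " + ", ".join(repr(c) for c in g.central_doses),
              "person_years = " + ", ".join(repr(p) for p in g.person_years),
              "n_individuals = " + ", ".join(str(n) for n in g.n_individuals)]
    for i, r in enumerate(config.risk_models, start=1):
        lines += ["", f"[risk r{i}]", f"form = {r.form}",
                  f"alpha = {r.alpha!r}", f"beta = {r.beta!r}"]
    for i, ec in enumerate(config.scenarios, start=1):
        lines += ["", f"[scenario s{i}]",
                  f"berkson_shared = {ec.sigma_share_berkson!r}",
                  f"berkson_unshared = {ec.sigma_unshare_berkson!r}",
                  f"classical_shared = {ec.sigma_share_class!r}",
                  f"classical_unshared = {ec.sigma_unshare_class!r}"]
    b = config.bma_settings
    lines += ["", "[bma]"]
    for f in dataclass_fields(BmaSettings):
        if f.name in _BMA_KEYS:
            lines.append(f"{f.name} = {getattr(b, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
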