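"""Run configuration: YAML/JSON config files resolved to explicit settings.

Recognised keys::

    id_name: SUBJECT_ID
    na_severity: informational | fail
    meaning_pattern: missing
    missing_codes:
      global: ["-9999", "-4444"]
      per_variable:
        AGE: ["-7777"]
    disable_checks: [row_check]
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .checks import PANEL_ORDER, CheckConfig, MissingCodeSpec
from .errors import ConfigError


def load_config(path=None, **overrides) -> CheckConfig:
    """Load a config file (YAML or JSON by content) and apply overrides.

    ``overrides`` accepts the same keys as the file plus ``global_codes``
    (an iterable replacing the global missing-code set).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError:
            try:
                raw = json.loads(text)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"{path}: neither valid YAML nor JSON") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    mc = raw.get("missing_codes") or {}
    if not isinstance(mc, dict):
        raise ConfigError("missing_codes must be a mapping with 'global'/'per_variable'")
    codes = MissingCodeSpec()
    if "global" in mc:
        codes.global_codes = {str(c) for c in mc["global"]}
    if "global_codes" in raw:
        codes.global_codes = {str(c) for c in raw["global_codes"]}
    for name, lst in (mc.get("per_variable") or {}).items():
        codes.per_variable[str(name)] = {str(c) for c in lst}
    if "meaning_pattern" in raw:
        codes.meaning_pattern = str(raw["meaning_pattern"])

    severity = str(raw.get("na_severity", "informational"))
    if severity not in ("informational", "fail"):
        raise ConfigError(f"na_severity must be 'informational' or 'fail', got {severity!r}")
    disabled = {str(c) for c in raw.get("disable_checks", [])}
    unknown = disabled - set(PANEL_ORDER)
    if unknown:
        raise ConfigError(f"unknown check name(s) in disable_checks: {sorted(unknown)}")

    return CheckConfig(
        codes=codes,
        id_name=str(raw.get("id_name", "SUBJECT_ID")),
        na_severity=severity,
        disabled_checks=disabled,
    )
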