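"""Structured text configuration (INI sections -> key/value) with schema
validation, and stderr logging setup.

Resolution order is: built-in defaults < config file < explicit function
arguments.  Every stochastic operation in the package logs its seed.
"""

from __future__ import annotations

import configparser
import logging
import sys
from pathlib import Path

from .errors import CalcipairError

_BOOL_TRUE = {"1", "true", "t", "yes", "on"}
_BOOL_FALSE = {"0", "false", "f", "no", "off"}


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to standard error with a compact format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("calcipair")
    root.handlers[:] = [handler]
    root.setLevel(level)


def _coerce(value: str, typ: type):
    if typ is bool:
        low = value.strip().lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise ValueError(f"not a boolean: {value!r}")
    return typ(value)


def load_config(path: str | Path, schema: dict[str, dict[str, type]]) -> dict[str, dict]:
    """Load and validate a sectioned key/value config file.

    ``schema`` maps section name -> {key: type}.  Unknown sections or keys and
    type mismatches raise :class:`CalcipairError` naming the offender.
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise CalcipairError(f"config file not found: {path}")
    result: dict[str, dict] = {}
    for section in parser.sections():
        if section not in schema:
            raise CalcipairError(
                f"unknown config section [{section}]; expected one of {sorted(schema)}"
            )
        result[section] = {}
        for key, raw in parser.items(section):
            if key not in schema[section]:
                raise CalcipairError(
                    f"unknown key {key!r} in section [{section}]; "
                    f"expected one of {sorted(schema[section])}"
                )
            try:
                result[section][key] = _coerce(raw, schema[section][key])
            except ValueError as exc:
                raise CalcipairError(
                    f"config [{section}] {key} = {raw!r}: {exc}"
                ) from exc
    return result
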