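"""File I/O helpers, validation entry points and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

from .dataset import ExperimentDataset

__all__ = ["load_dataset", "save_json", "run_manifest", "EXIT_CONFIG", "EXIT_DATA", "EXIT_NOCONV"]

# CLI exit codes: configuration error / data error / non-convergence
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_NOCONV = 4


def load_dataset(path: str | Path) -> ExperimentDataset:
    """Load and validate an experiment dataset CSV.

    Raises :class:`~filtergate.dataset.DatasetSchemaError` with the first
    offending row/column on any schema violation.
    """
    return ExperimentDataset.load_csv(path)


def save_json(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(command: str, inputs: dict[str, str | Path], seed: int | None) -> dict:
    """Machine-readable provenance record for one CLI run."""
    import numpy
    import scipy

    from . import __version__

    return {
        "command": command,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if Path(p).exists()
        },
        "versions": {
            "filtergate": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
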