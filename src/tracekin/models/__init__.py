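"""Shipped networks: the hepatocyte glucose/fructose demonstration model,
small toy fixtures with analytically checkable behaviour, and the
synthetic-data generator."""

from importlib import resources
from pathlib import Path

from .hepato import condition_library, demo_observables, make_demo_model
from .synthetic import generate_synthetic_dataset
from .toys import make_toy

__all__ = [
    "make_demo_model",
    "condition_library",
    "demo_observables",
    "make_toy",
    "generate_synthetic_dataset",
    "data_path",
]


def data_path(filename: str) -> Path:
    """Path to a shipped native-config data file (e.g. 'hepatocyte_demo.yaml')."""
    p = Path(resources.files(__name__) / "data" / filename)
    if not p.exists():
        raise FileNotFoundError(filename)
    return p
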