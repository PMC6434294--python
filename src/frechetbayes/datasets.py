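"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .distribution import Sample
from .io import read_sample

__all__ = ["head_neck_survival"]


def head_neck_survival() -> Sample:
    """The 44 survival times (days) of head-and-neck cancer patients.

    A right-skewed classic benchmark for heavy-tailed survival models;
    patients received combined radiotherapy and chemotherapy.
    """
    ref = resources.files("frechetbayes").joinpath("data/head_neck_survival.txt")
    with resources.as_file(ref) as path:
        return read_sample(path)
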