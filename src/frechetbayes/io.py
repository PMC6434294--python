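"""Reading univariate samples from plain-text or single-column CSV files."""

from __future__ import annotations

from pathlib import Path

from .distribution import Sample

__all__ = ["read_sample"]


def read_sample(path) -> Sample:
    """Read one real value per row; blank lines and ``#`` comments are ignored.

    A trailing comma (single-column CSV) and a non-numeric header row are
    tolerated.  Parse failures report the offending line number.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip().rstrip(",")
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {line!r} as a number"
                ) from None
    if not values:
        raise ValueError(f"{path}: no data rows found")
    return Sample.from_iterable(values, source=str(path))
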