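"""Minimal Praat TextGrid interval-tier I/O plus a CSV alternative.

Only the long ("ooTextFile") TextGrid format with interval tiers is
supported — enough to exchange phone alignments with Praat and forced
aligners.  Times inside TextGrids are seconds; this module converts to the
package's millisecond convention.  The CSV alternative uses columns
``utterance_id, phone, start_ms, end_ms``.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .labeling import PhoneInterval

__all__ = ["read_textgrid", "write_textgrid", "read_intervals_csv", "write_intervals_csv"]

_NUM = r"(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"


def read_textgrid(path: str | Path, tier: str = "phones") -> list[PhoneInterval]:
    """Read one interval tier of a long-format TextGrid as phone intervals.

    Zero-length intervals are dropped; empty labels are kept (they are
    silence markers for the labeling rules).
    """
    text = Path(path).read_text(encoding="utf-8")
    if "ooTextFile" not in text.split("\n", 1)[0]:
        raise ValueError(f"{path}: not a Praat TextGrid (missing ooTextFile header)")
    tier_pat = re.compile(
        r'class\s*=\s*"IntervalTier"\s*\n\s*name\s*=\s*"([^"]*)"', re.S
    )
    spans = [(m.group(1), m.start()) for m in tier_pat.finditer(text)]
    if not spans:
        raise ValueError(f"{path}: no IntervalTier found")
    names = [n for n, _ in spans]
    try:
        idx = names.index(tier)
    except ValueError:
        raise ValueError(f"{path}: tier {tier!r} not found (tiers: {names})") from None
    start = spans[idx][1]
    end = spans[idx + 1][1] if idx + 1 < len(spans) else len(text)
    block = text[start:end]
    iv_pat = re.compile(
        r"xmin\s*=\s*" + _NUM + r"\s*\n\s*xmax\s*=\s*" + _NUM
        + r'\s*\n\s*text\s*=\s*"((?:[^"]|"")*)"',
        re.S,
    )
    out = []
    for m in iv_pat.finditer(block):
        xmin, xmax = float(m.group(1)), float(m.group(2))
        if xmax <= xmin:
            continue
        label = m.group(3).replace('""', '"')
        out.append(PhoneInterval(label=label, start_ms=1000 * xmin, end_ms=1000 * xmax))
    return out


def write_textgrid(
    path: str | Path, intervals: list[PhoneInterval], tier: str = "phones"
) -> Path:
    """Write phone intervals as a single-tier long-format TextGrid."""
    if not intervals:
        raise ValueError("cannot write an empty TextGrid")
    ivs = sorted(intervals, key=lambda iv: iv.start_ms)
    xmin, xmax = ivs[0].start_ms / 1000, ivs[-1].end_ms / 1000
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier}"',
        f"        xmin = {xmin:.6f}",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(ivs)}",
    ]
    for i, iv in enumerate(ivs, start=1):
        esc = iv.label.replace('"', '""')
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {iv.start_ms / 1000:.6f}",
            f"            xmax = {iv.end_ms / 1000:.6f}",
            f'            text = "{esc}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return Path(path)


def read_intervals_csv(path: str | Path) -> dict[str, list[PhoneInterval]]:
    """Read the tabular interval format, grouped by utterance_id."""
    df = pd.read_csv(path, keep_default_na=False)
    required = {"utterance_id", "phone", "start_ms", "end_ms"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: interval CSV needs columns {sorted(required)}")
    out: dict[str, list[PhoneInterval]] = {}
    for utt, grp in df.groupby("utterance_id", sort=False):
        out[str(utt)] = [
            PhoneInterval(label=str(r.phone), start_ms=float(r.start_ms), end_ms=float(r.end_ms))
            for r in grp.itertuples()
        ]
    return out


def write_intervals_csv(
    path: str | Path, intervals_by_utt: dict[str, list[PhoneInterval]]
) -> Path:
    rows = [
        {"utterance_id": utt, "phone": iv.label, "start_ms": iv.start_ms, "end_ms": iv.end_ms}
        for utt, ivs in intervals_by_utt.items()
        for iv in ivs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
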