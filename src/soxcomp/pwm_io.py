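"""PWM input: MEME minimal format and plain 4-column probability text."""

from __future__ import annotations

import numpy as np

from .motifs import PWM


def read_meme_minimal(path) -> list[PWM]:
    """Read PWMs from a MEME minimal-format file.

    The letter-probability matrices are read at full precision (no
    quantization through nsites-scaled counts).
    """
    background = np.full(4, 0.25)
    out: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    expect_bg = False

    def flush():
        if name is not None and rows:
            out.append(PWM(name=name, probs=np.asarray(rows),
                           background=background.copy()))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if expect_bg and line:
                fields = line.split()
                bg = {fields[i]: float(fields[i + 1])
                      for i in range(0, len(fields) - 1, 2)}
                background = np.array([bg.get(b, 0.25) for b in "ACGT"])
                expect_bg = False
                continue
            if line.startswith("Background letter frequencies"):
                expect_bg = True
            elif line.startswith("MOTIF"):
                flush()
                name, rows = line.split()[1], []
            elif name is not None and line and line[0] in "0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError("expected 4 probabilities per row")
                rows.append(vals)
    flush()
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def read_probability_matrix(path, name: str | None = None) -> PWM:
    """Read a PWM from whitespace-separated text, one row per position,
    columns A C G T (probabilities)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">")):
                continue
            vals = [float(v) for v in line.split()]
            if len(vals) != 4:
                raise ValueError("expected 4 columns (A C G T)")
            rows.append(vals)
    if not rows:
        raise ValueError(f"no matrix rows in {path}")
    probs = np.asarray(rows)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWM(name=name or "motif", probs=probs)


def write_probability_matrix(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {pwm.name}\n")
        for row in pwm.probs:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
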