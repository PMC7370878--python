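"""Position weight matrices: CIS-BP-style text I/O and normalization.

Raw position frequency matrices are normalized in three steps: entries
below a tolerance are clamped up to it and each position rescaled to sum
to one; positions are renormalized to one; a pseudocount is added and
positions renormalized once more. The result has every entry strictly
positive and every position summing to one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"


@dataclass
class PWM:
    motif_id: str
    tf_name: str
    matrix: np.ndarray  # positions x 4, rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: PWM must be positions x 4")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.tf_name, self.matrix[::-1, ::-1])


def normalize_pwm(
    motif_id: str,
    tf_name: str,
    raw: np.ndarray,
    tolerance: float = 1e-6,
    pseudocount: float = 0.008,
) -> PWM:
    """Normalize a raw frequency matrix into a proper PWM (see module doc)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 4 or raw.shape[0] < 1:
        raise ValueError(f"{motif_id}: raw matrix must be positions x 4")
    if (raw < 0).any():
        raise ValueError(f"{motif_id}: negative frequencies")
    sums = raw.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"{motif_id}: all-zero frequency at position {zero[0]}")
    m = np.maximum(raw / sums[:, None], tolerance)
    m = m / m.sum(axis=1, keepdims=True)
    m = m + pseudocount
    m = m / m.sum(axis=1, keepdims=True)
    return PWM(motif_id, tf_name, m)


def read_pwm_file(path, tolerance: float = 1e-6, pseudocount: float = 0.008) -> PWM:
    """Read one CIS-BP-style PWM text file.

    Layout: optional '#'-comment lines, a 'Motif<TAB>id' line, a
    'TF<TAB>name' line, a 'Pos A C G T' header, then one row per position.
    The raw frequencies are normalized on read.
    """
    motif_id = tf_name = ""
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "Motif":
                motif_id = cols[1]
            elif cols[0] == "TF":
                tf_name = cols[1]
            elif cols[0] == "Pos":
                continue
            else:
                rows.append([float(v) for v in cols[1:5]])
    if not rows:
        raise ValueError(f"{path}: no frequency rows")
    return normalize_pwm(motif_id or str(path), tf_name, np.array(rows),
                         tolerance=tolerance, pseudocount=pseudocount)


def write_pwm_file(pwm: PWM, path, raw: np.ndarray | None = None) -> None:
    """Write a PWM (or the raw frequencies it came from) in the same dialect."""
    matrix = pwm.matrix if raw is None else np.asarray(raw, float)
    with open(path, "w") as fh:
        fh.write(f"Motif\t{pwm.motif_id}\n")
        fh.write(f"TF\t{pwm.tf_name}\n")
        fh.write("Pos\tA\tC\tG\tT\n")
        for i, row in enumerate(matrix, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
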