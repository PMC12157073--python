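"""Readers and writers for the formats the tool touches.

Genomes come in as FASTA; per-cytosine bisulfite calls as Bismark-style
cytosine reports (tab-separated ``chrom pos strand n_meth n_unmeth context
[tricontext]``, 1-based positions); predictions go out as a TSV that
round-trips losslessly; learned motifs go out in MEME minimal format.

Coordinates are 1-based inclusive in every file format (the Bismark
convention); the conversion to 0-based indices happens inside
:mod:`methynet.encode` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSequence", "FastaFormatError", "ReportFormatError",
    "read_fasta", "write_fasta", "read_cytosine_report",
    "write_cytosine_report", "write_predictions", "read_predictions",
    "write_meme", "write_bedgraph", "BASE_ORDER", "NA_TOKEN",
]

#: One-hot channel order used throughout: A, T, G, C.
BASE_ORDER = "ATGC"
#: Integer code for each base; anything else maps to the N code (4).
BASE_CODES = {"A": 0, "T": 1, "G": 2, "C": 3, "N": 4}
N_CODE = 4
#: Missing-state literal in all text outputs.
NA_TOKEN = "NA"

_CODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _CODE_LUT[ord(_b)] = _c
# complement under the A,T,G,C,N coding: A<->T, G<->C, N->N
COMPLEMENT_CODES = np.array([1, 0, 3, 2, 4], dtype=np.uint8)

_NORMALIZE = {c: c if chr(c) in "ACGTN" else ord("N") for c in range(256)}


class FastaFormatError(ValueError):
    pass


class ReportFormatError(ValueError):
    pass


@dataclass
class GenomeSequence:
    """One chromosome: uppercase sequence over {A,C,G,T,N}."""

    name: str
    sequence: str
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        # uppercase and collapse anything outside {A,C,G,T} to N
        self.sequence = self.sequence.upper().translate(_NORMALIZE)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """uint8 base codes (A=0, T=1, G=2, C=3, N/other=4)."""
        if self._codes is None:
            raw = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
            self._codes = _CODE_LUT[raw]
        return self._codes


def read_fasta(path) -> dict[str, GenomeSequence]:
    """Parse a FASTA file into an ordered ``{name: GenomeSequence}`` mapping.

    Sequences are uppercased; IUPAC ambiguity codes collapse to ``N``.
    Duplicate record ids, headerless leading sequence, empty headers and
    empty records raise :class:`FastaFormatError` naming the offending line.
    """
    records: dict[str, GenomeSequence] = {}
    name = None
    chunks: list[str] = []
    header_line = 0

    def _flush():
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(
                f"record '{name}' at line {header_line} has an empty sequence")
        records[name] = GenomeSequence(name, seq)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not name:
                    raise FastaFormatError(f"empty FASTA header at line {lineno}")
                if name in records:
                    raise FastaFormatError(
                        f"duplicate sequence id '{name}' at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"sequence data before any header at line {lineno}")
                chunks.append(line)
    _flush()
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(genomes, path, width: int = 70) -> None:
    seqs = genomes.values() if isinstance(genomes, dict) else genomes
    with open(path, "w") as fh:
        for g in seqs:
            fh.write(f">{g.name}\n")
            for s in range(0, len(g.sequence), width):
                fh.write(g.sequence[s : s + width] + "\n")


REPORT_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style cytosine report.

    Expected tab-separated columns: chrom, 1-based pos, strand (+/-),
    methylated read count, unmethylated read count, context (optional),
    trinucleotide context (optional, ignored).  Rows come back sorted by
    (chrom, pos); ``df.attrs['context_present']`` records whether a context
    column was supplied.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 5:
        raise ReportFormatError(
            f"{path}: expected >=5 tab-separated columns, found {df.shape[1]}")
    context_present = df.shape[1] >= 6
    df = df.iloc[:, :6] if context_present else df.iloc[:, :5]
    df.columns = REPORT_COLUMNS[: df.shape[1]]

    def _int_col(col, minimum):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < minimum)
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ReportFormatError(
                f"{path} line {line}: invalid value {df[col][bad.idxmax()]!r} "
                f"in column '{col}' (integer >= {minimum} required)")
        return vals.astype(np.int64)

    df["pos"] = _int_col("pos", 1)
    df["n_meth"] = _int_col("n_meth", 0)
    df["n_unmeth"] = _int_col("n_unmeth", 0)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise ReportFormatError(
            f"{path} line {line}: strand must be '+' or '-', "
            f"got {df['strand'][bad_strand.idxmax()]!r}")
    if not context_present:
        df["context"] = pd.NA
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df.attrs["context_present"] = context_present
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=[c for c in REPORT_COLUMNS if c in df.columns])


PREDICTION_COLUMNS = ["chrom", "pos", "strand", "context",
                      "observed_state", "pred_prob", "imputed_state"]


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write a methylome table (observed / probability / imputed columns).

    Probabilities must lie in [0, 1] where present; missing values serialize
    as the literal ``NA``.  Floats use shortest round-trip repr so that
    ``read_predictions(write_predictions(t)) == t``.
    """
    probs = pd.to_numeric(table["pred_prob"], errors="coerce")
    finite = probs.dropna()
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("pred_prob outside [0, 1]")
    out = table[PREDICTION_COLUMNS].copy()
    for col in ("observed_state", "imputed_state"):
        out[col] = [
            NA_TOKEN if pd.isna(v) else str(int(v)) for v in out[col]
        ]
    out["pred_prob"] = [NA_TOKEN if pd.isna(v) else repr(float(v)) for v in probs]
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    na_cols = {c: [NA_TOKEN] for c in ("context", "observed_state",
                                       "pred_prob", "imputed_state")}
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str},
                     na_values=na_cols, keep_default_na=False)
    for col in ("observed_state", "imputed_state"):
        df[col] = df[col].astype("float64")
    return df


def write_meme(motifs, path, alphabet: str = "ACGT") -> None:
    """Write motifs (objects with ``pwm``, ``filter_index``, ``n_windows``)
    to a MEME minimal-format file.

    PWM rows are probability vectors over A,C,G,T and must each sum to 1
    within 1e-6.
    """
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            pwm = np.asarray(m.pwm, dtype=float)
            if pwm.ndim != 2 or pwm.shape[1] != len(alphabet):
                raise ValueError(f"PWM for filter {m.filter_index} has shape {pwm.shape}")
            sums = pwm.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError(
                    f"PWM rows for filter {m.filter_index} do not sum to 1 "
                    f"(max deviation {np.max(np.abs(sums - 1.0)):.2e})")
            nsites = max(int(getattr(m, "n_windows", 0)), 1)
            fh.write(f"MOTIF filter_{m.filter_index}\n")
            fh.write(f"letter-probability matrix: alength= {pwm.shape[1]} "
                     f"w= {pwm.shape[0]} nsites= {nsites} E= 0\n")
            for row in pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def write_bedgraph(table: pd.DataFrame, path, value_col: str = "pred_prob",
                   track_name: str = "methylation") -> None:
    """Export one column of a methylome table as a bedGraph probability track."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        sub = table.dropna(subset=[value_col])
        for chrom, pos, val in zip(sub["chrom"], sub["pos"], sub[value_col]):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{float(val):g}\n")
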