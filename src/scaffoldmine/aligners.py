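"""Pluggable multiple-sequence-alignment backends.

Profile construction and predict-time feature mapping both need a multiple
alignment; the package does not implement one itself.  Any object with an
``align(sequences) -> list[str]`` method satisfies the contract.  Two
implementations are provided: a subprocess wrapper around ``mafft`` and a
trivial gap-padding aligner for sequence sets that are already columnar
(equal length), which is the common case for motif-style fixtures.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

GAP = "-"


@runtime_checkable
class AlignerContract(Protocol):
    def align(self, sequences: Sequence[str]) -> list[str]:
        """Return one aligned (gapped) string per input sequence, all equal length."""


class PrealignedAligner:
    """Pads sequences with trailing gaps to a common length.

    Correct only when the inputs are already positionally homologous
    (e.g. fixed-length motif families); it performs no real alignment.
    """

    def align(self, sequences: Sequence[str]) -> list[str]:
        if not sequences:
            return []
        width = max(len(s) for s in sequences)
        return [s + GAP * (width - len(s)) for s in sequences]


class MafftAligner:
    """Align via the ``mafft`` executable (FASTA in, FASTA out)."""

    def __init__(self, executable: str = "mafft", extra_args: Sequence[str] = ("--auto",)):
        self.executable = executable
        self.extra_args = list(extra_args)

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def align(self, sequences: Sequence[str]) -> list[str]:
        if not sequences:
            return []
        if len(sequences) == 1:
            return [sequences[0]]
        with tempfile.TemporaryDirectory() as tmp:
            infile = Path(tmp) / "in.fasta"
            infile.write_text(
                "".join(f">s{i}\n{seq}\n" for i, seq in enumerate(sequences))
            )
            proc = subprocess.run(
                [self.executable, *self.extra_args, str(infile)],
                capture_output=True,
                text=True,
                check=True,
            )
        out: dict[str, str] = {}
        name = None
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                name = line[1:].strip()
                out[name] = ""
            elif name is not None:
                out[name] += line.strip()
        return [out[f"s{i}"].upper() for i in range(len(sequences))]


def default_aligner() -> AlignerContract:
    """Mafft when installed, else the padding fallback."""
    mafft = MafftAligner()
    return mafft if mafft.available() else PrealignedAligner()
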