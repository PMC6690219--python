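"""Pluggable external short-read aligner.

The pipeline only requires an aligner that reports partial matches as soft
clips in standard SAM; ``bwa mem`` is the default command.  Every pipeline
stage alternatively accepts a pre-computed SAM path, so the core logic is
fully testable without any aligner binary.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


class AlignerError(RuntimeError):
    """The external aligner failed."""


class AlignerUnavailableError(AlignerError):
    """No aligner binary found and no pre-computed SAM supplied."""


@dataclass
class BwaMem:
    """Thin wrapper over the ``bwa`` binary (``index`` + ``mem``)."""

    executable: str = "bwa"
    threads: int = 1
    extra_args: Sequence[str] = ()

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def _run(self, cmd: list[str], stdout=None) -> None:
        try:
            result = subprocess.run(
                cmd, stdout=stdout, stderr=subprocess.PIPE, check=False
            )
        except FileNotFoundError as exc:
            raise AlignerUnavailableError(
                f"aligner executable {self.executable!r} not found on PATH"
            ) from exc
        if result.returncode != 0:
            tail = result.stderr.decode(errors="replace")[-2000:]
            raise AlignerError(f"{' '.join(cmd)} failed:\n{tail}")

    def index(self, reference: str | Path) -> None:
        """Build the BWT index unless an up-to-date one already exists."""
        ref = Path(reference)
        index_files = [ref.with_suffix(ref.suffix + ext) for ext in
                       (".amb", ".ann", ".bwt", ".pac", ".sa")]
        ref_mtime = ref.stat().st_mtime
        if all(f.exists() and f.stat().st_mtime >= ref_mtime for f in index_files):
            return
        self._run([self.executable, "index", str(ref)])

    def map_reads(
        self, reference: str | Path, fastqs: Sequence[str | Path], out_sam: str | Path
    ) -> None:
        """Map one (single-end) or two (paired-end) FASTQ files to *reference*."""
        if not self.available():
            raise AlignerUnavailableError(
                f"aligner executable {self.executable!r} not found on PATH"
            )
        if not 1 <= len(fastqs) <= 2:
            raise ValueError("map_reads takes one or two FASTQ files")
        self.index(reference)
        cmd = [
            self.executable,
            "mem",
            "-t",
            str(self.threads),
            *self.extra_args,
            str(reference),
            *[str(f) for f in fastqs],
        ]
        with open(out_sam, "wb") as out:
            self._run(cmd, stdout=out)

    def map_paired(
        self, reference: str | Path, fastq1: str | Path, fastq2: str | Path,
        out_sam: str | Path,
    ) -> None:
        self.map_reads(reference, [fastq1, fastq2], out_sam)

    def map_single(
        self, reference: str | Path, fastq: str | Path, out_sam: str | Path
    ) -> None:
        self.map_reads(reference, [fastq], out_sam)
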