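"""External aligner adapters.

Tree-inference benchmarks need a realignment step between the simulator's
ungapped sequences and the filters; mafft is the bundled default.  The
adapter returns a :class:`~filterbench.core.Alignment` whose rows spell the
input sequences, so all downstream accuracy metrics apply directly.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

from .core import Alignment, write_fasta

__all__ = ["mafft_align", "make_aligner", "AlignerError"]


class AlignerError(RuntimeError):
    pass


#: default mafft mode: G-INS-i, the accurate global-alignment mode, which
#: fits simulated families that are homologous over their whole length
DEFAULT_MAFFT_ARGS = ("--globalpair", "--maxiterate", "1000")


def mafft_align(seqs: Mapping[str, str],
                args: Sequence[str] = DEFAULT_MAFFT_ARGS,
                executable: str = "mafft",
                workdir: Optional[str | Path] = None) -> Alignment:
    """Align a mapping of id -> ungapped sequence with mafft.

    The default arguments select G-INS-i (global pairwise information,
    iterative refinement).  Input order is preserved; output is parsed
    from stdout.
    """
    with tempfile.TemporaryDirectory() as tmp:
        work = Path(workdir) if workdir is not None else Path(tmp)
        work.mkdir(parents=True, exist_ok=True)
        inp = work / "unaligned.fasta"
        write_fasta(seqs, inp)
        argv = [executable, *args, "--amino", str(inp)]
        try:
            proc = subprocess.run(argv, capture_output=True, text=True)
        except FileNotFoundError as exc:
            raise AlignerError(f"aligner executable not found: {executable}") from exc
        if proc.returncode != 0:
            raise AlignerError(
                f"mafft exited {proc.returncode}: {proc.stderr[-500:]}")
        return _parse_fasta_text(proc.stdout, list(seqs))


def _parse_fasta_text(text: str, expected_ids: list) -> Alignment:
    ids, rows, current = [], [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if current:
                rows.append("".join(current))
                current = []
            ids.append(line[1:].split()[0])
        else:
            current.append(line.strip())
    if current:
        rows.append("".join(current))
    if set(ids) != set(expected_ids):
        raise AlignerError("aligner dropped or renamed sequences")
    order = {name: k for k, name in enumerate(ids)}
    rows = [rows[order[name]] for name in expected_ids]
    return Alignment(ids=list(expected_ids), rows=rows, alphabet="aa")


def make_aligner(args: Sequence[str] = DEFAULT_MAFFT_ARGS,
                 executable: str = "mafft") -> Callable[[Mapping[str, str]], Alignment]:
    """Bind mafft options into a ``seqs -> Alignment`` callable."""

    def aligner(seqs: Mapping[str, str]) -> Alignment:
        return mafft_align(seqs, args=args, executable=executable)

    return aligner
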