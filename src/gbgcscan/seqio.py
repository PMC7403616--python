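"""Small FASTA helpers shared by the pipeline and the CLI."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_alignment_dir(directory: str | Path) -> dict[str, dict[str, str]]:
    """Read every ``*.fasta`` in a directory; keys are file stems."""
    return {
        f.stem: read_fasta(f)
        for f in sorted(Path(directory).glob("*.fasta"))
    }


def read_family_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Group family sequences by family id (sequence ids are
    ``<family>_<member>``)."""
    grouped: dict[str, dict[str, str]] = {}
    for sid, seq in read_fasta(path).items():
        famid = "_".join(sid.split("_")[:-1])
        grouped.setdefault(famid, {})[sid] = seq
    return grouped
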