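"""Read and write the Genepop text format for diploid genotypes.

Genepop files carry a title line, one locus name per line, then one
``Pop`` block per population with lines ``individual ,  AAABBB ...`` where
each genotype is two concatenated fixed-width allele codes (2- or 3-digit)
and an all-zero code marks a missing genotype.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .popgen import MISSING, GenotypeTable


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    title: str = "thermotrout genotypes",
    digits: int = 3,
) -> None:
    """Write a :class:`GenotypeTable` as a Genepop file.

    Population labels are not part of the format; they are preserved by
    prefixing each individual id with ``label_`` inside its Pop block.
    """
    if digits not in (2, 3):
        raise ValueError("Genepop allele coding is 2 or 3 digits")
    if np.any(table.genotypes >= 10**digits):
        raise ValueError(f"allele labels do not fit {digits}-digit coding")
    lines = [title]
    lines.extend(table.loci)
    for pop in table.populations:
        lines.append("Pop")
        for i in np.flatnonzero(table.pop_labels == pop):
            codes = []
            for a, b in table.genotypes[i]:
                a = 0 if a == MISSING else a
                b = 0 if b == MISSING else b
                codes.append(f"{a:0{digits}d}{b:0{digits}d}")
            name = table.individuals[i]
            if not name.startswith(f"{pop}_"):
                name = f"{pop}_{name}"
            lines.append(f"{name} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path, pop_labels: list[str] | None = None) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Population labels come from ``pop_labels`` (one per Pop block), else
    from the ``label_`` prefix of each block's individual names, else
    ``Pop1..PopN``. Locus names may be listed one per line or
    comma-separated on a single line.
    """
    raw = Path(path).read_text().splitlines()
    if len(raw) < 3:
        raise ValueError("not a Genepop file: too few lines")
    body = raw[1:]
    pop_starts = [i for i, l in enumerate(body) if l.strip().lower() == "pop"]
    if not pop_starts:
        raise ValueError("no Pop line found")
    loci: list[str] = []
    for line in body[: pop_starts[0]]:
        loci.extend(x.strip() for x in line.split(",") if x.strip())
    digits = None
    individuals, genotypes, labels = [], [], []
    blocks = pop_starts + [len(body)]
    for bi in range(len(pop_starts)):
        block = [l for l in body[blocks[bi] + 1 : blocks[bi + 1]] if l.strip()]
        block_names = []
        for line in block:
            name, _, geno = line.partition(",")
            name = name.strip()
            codes = geno.split()
            if len(codes) != len(loci):
                raise ValueError(
                    f"individual {name!r} has {len(codes)} genotypes for {len(loci)} loci"
                )
            if digits is None:
                digits = len(codes[0]) // 2
            row = []
            for code in codes:
                a, b = int(code[:digits]), int(code[digits:])
                row.append((MISSING, MISSING) if a == 0 or b == 0 else (a, b))
            individuals.append(name)
            genotypes.append(row)
            block_names.append(name)
        if pop_labels is not None:
            label = pop_labels[bi]
        else:
            prefixes = {n.split("_")[0] for n in block_names}
            label = prefixes.pop() if len(prefixes) == 1 else f"Pop{bi + 1}"
        labels.extend([label] * len(block_names))
    return GenotypeTable(
        individuals,
        loci,
        np.array(genotypes, dtype=int),
        np.array(labels, dtype=object),
    )
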