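"""Genome and probe-grid model for aCGH profiles.

A :class:`GenomeModel` is the fixed probe layout shared by all samples of a
cohort: an ordered list of chromosomes and, per chromosome, the sorted
genomic positions of the array probes.  All internal coordinates are 0-based
half-open; file formats state their own convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: natural human chromosome order; toy genomes may override
HUMAN_CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]


def chromosome_sort_key(name: str, order: list[str] | None = None):
    """Sort key placing chromosomes in natural order (1..22, X, Y), then others."""
    order = order if order is not None else HUMAN_CHROM_ORDER
    name = str(name)
    stripped = name[3:] if name.lower().startswith("chr") else name
    if stripped in order:
        return (0, order.index(stripped), "")
    return (1, 0, stripped)


@dataclass
class GenomeModel:
    """Probe grid: chromosomes with lengths and sorted probe positions.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    probe_positions
        Mapping chromosome name -> strictly increasing probe start positions
        (bp, 0-based).
    probe_length
        Footprint of one oligo in bp (probe end = start + probe_length).
    """

    chromosomes: list[tuple[str, int]]
    probe_positions: dict[str, np.ndarray]
    probe_length: int = 60
    chrom_order: list[str] = field(default_factory=lambda: list(HUMAN_CHROM_ORDER))

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if set(self.probe_positions) != set(names):
            raise ValueError("probe_positions keys must match chromosome names")
        for name, length in self.chromosomes:
            pos = np.asarray(self.probe_positions[name], dtype=np.int64)
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"probe positions not strictly increasing on {name}")
            if pos.size and (pos[0] < 0 or pos[-1] + self.probe_length > length):
                raise ValueError(f"probe outside chromosome {name}")
            self.probe_positions[name] = pos

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def probes_total(self) -> int:
        return int(sum(len(self.probe_positions[c]) for c in self.chrom_names))

    def probe_table(self):
        """Return a DataFrame of all probes: ProbeName, Chromosome, Start, End."""
        import pandas as pd

        frames = []
        for name in self.chrom_names:
            pos = self.probe_positions[name]
            frames.append(
                pd.DataFrame(
                    {
                        "ProbeName": [f"P_{name}_{i:06d}" for i in range(len(pos))],
                        "Chromosome": name,
                        "Start": pos,
                        "End": pos + self.probe_length,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def toy(
        cls,
        n_chromosomes: int = 4,
        probes_per_chromosome: int = 2500,
        chromosome_length: int = 100_000_000,
    ) -> "GenomeModel":
        """Evenly spaced toy genome (default 4 x 2,500 probes) for fast tests.

        Probe spacing on the default layout is 40 kb, the same order of
        magnitude as a 60K whole-genome CGH array.
        """
        chroms = [(str(i + 1), chromosome_length) for i in range(n_chromosomes)]
        spacing = chromosome_length // (probes_per_chromosome + 1)
        pos = np.arange(1, probes_per_chromosome + 1, dtype=np.int64) * spacing
        positions = {name: pos.copy() for name, _ in chroms}
        order = [name for name, _ in chroms]
        return cls(chroms, positions, chrom_order=order)

    @classmethod
    def full_human(cls, probes_total: int = 60_000) -> "GenomeModel":
        """hg19-sized autosome+XY grid with probes spread proportional to length.

        Provided for realistic-scale runs; the toy genome is the default
        everywhere because it keeps simulations fast.
        """
        lengths = {
            "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
            "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
            "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
            "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
            "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
            "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
        }
        total = sum(lengths.values())
        chroms = [(n, l) for n, l in lengths.items()]
        positions = {}
        for name, length in chroms:
            n_probes = max(1, int(round(probes_total * length / total)))
            spacing = length // (n_probes + 1)
            positions[name] = np.arange(1, n_probes + 1, dtype=np.int64) * spacing
        return cls(chroms, positions)
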