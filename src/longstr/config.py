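"""Run configuration: every tunable of the genotyping/composition pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Tunables with their documented defaults.

    flank_bp
        Flank length of the excised artificial reference (bp); large
        flanks give the realigner unique anchor sequence.
    span_margin
        Margin around the locus a read's alignment must fully cover to
        be collected (bp).
    mapq_min
        Minimum mapping quality of collected reads.
    merge_window_bp
        Window around the excision junction within which insertion
        operations are concatenated into the allele (bp); also the
        minimum anchored reference coverage required on each side.
    min_support
        Minimum reads supporting an allele call.
    exclusion_fraction / exclusion_dissimilarity
        Dendrogram subtree-exclusion rule: drop top-level subtrees
        holding less than this fraction of reads when the merge
        dissimilarity (edit distance scale) exceeds this value.
    hom_het_threshold / hom_het_rel
        Call het only when the final merge height exceeds
        max(hom_het_threshold, hom_het_rel x longer allele length).
    phasing
        ``auto`` (use HP tags when both haplotypes have >=2 tagged
        reads), ``force`` or ``off``.
    haploid_chroms
        Chromosomes genotyped as haploid (no allele splitting).
    top_n / bin_width / min_group
        Composition view parameters: palette size of the sequence
        view, profile binning width and minimum group size of the
        collapsed view.
    keep_outliers_in_consensus
        Report length outliers but keep them in the consensus input.
    """

    flank_bp: int = 5000
    span_margin: int = 100
    mapq_min: int = 5
    merge_window_bp: int = 25
    min_support: int = 2
    exclusion_fraction: float = 0.10
    exclusion_dissimilarity: float = 5.0
    hom_het_threshold: float = 5.0
    hom_het_rel: float = 0.05
    phasing: str = "auto"
    haploid_chroms: tuple[str, ...] = ()
    top_n: int = 10
    bin_width: float = 0.05
    min_group: int = 5
    keep_outliers_in_consensus: bool = False

    def __post_init__(self) -> None:
        if self.flank_bp < 1:
            raise ValueError("flank_bp must be >= 1")
        if self.phasing not in ("auto", "force", "off"):
            raise ValueError("phasing must be auto, force or off")
        for name in ("span_margin", "merge_window_bp", "min_support", "top_n", "min_group"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.exclusion_fraction <= 1:
            raise ValueError("exclusion_fraction must be in [0,1]")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "haploid_chroms":
                value = ",".join(value)
            lines.append(f"{f.name}={value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs = {}
        type_map = {f.name: f.type for f in fields(cls)}
        for key, value in raw.items():
            if key not in type_map:
                raise ValueError(f"unknown config key {key!r}")
            if key == "haploid_chroms":
                kwargs[key] = tuple(v for v in value.split(",") if v)
            elif key in ("phasing",):
                kwargs[key] = value
            elif key == "keep_outliers_in_consensus":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("flank_bp", "span_margin", "mapq_min", "merge_window_bp",
                         "min_support", "top_n", "min_group"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)
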