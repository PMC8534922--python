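"""End-to-end orchestration: config, logging, one report directory.

Stages (each toggleable): conservation profile, minimum-evolution trees
(joint and per-family), motif calling with logo matrices, and ancestral
reconstruction.  Every output file carries a '#' header naming the
parameters that produced it, and a run.log records progress; reruns with
identical inputs and seed are byte-identical apart from timestamps, which
only appear in the log.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ancestral import SubstitutionModel, marginal_posteriors, write_ancestral_fasta
from .conservation import conservation_profile, domain_identity_summary, profile_to_tsv
from .motifs import call_motifs, henikoff_weights, logo_matrix, motif_report
from .phylo import Correction, distance_matrix, me_tree, root_tree
from .records import Isoform
from .seqio import read_alignment, read_domain_annotations, read_isoform_map

log = logging.getLogger("paraloglens")


@dataclass
class RunConfig:
    alignment: str
    isoform_map: str
    ref1: str
    ref2: str
    out_dir: str = "paraloglens_run"
    alignment_format: str = "fasta"
    domains: str | None = None
    outgroup: list[str] = field(default_factory=list)
    correction: str = "poisson"
    min_cons: float = 0.5
    min_len: int = 10
    max_violations: int = 2
    background: str = "uniform"  # uniform | empirical
    pseudocount: float = 0.0
    model_pi: str = "uniform"  # uniform | empirical
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["conserve", "tree", "motifs", "ancestral"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for attr in ("alignment", "isoform_map"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if self.domains and not Path(self.domains).exists():
            raise FileNotFoundError(f"domains file not found: {self.domains}")
        if not (0.0 < self.min_cons <= 1.0):
            raise ValueError("min_cons must lie in (0, 1]")
        if self.correction.lower() not in ("p", "poisson"):
            raise ValueError("correction must be 'p' or 'poisson'")
        unknown = set(self.stages) - {"conserve", "tree", "motifs", "ancestral"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _setup_logging(out_dir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    console = logging.StreamHandler(sys.stderr)
    console.setLevel(logging.DEBUG if verbose else logging.INFO)
    console.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logfile = logging.FileHandler(out_dir / "run.log", mode="w")
    logfile.setLevel(logging.DEBUG)
    logfile.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(console)
    log.addHandler(logfile)


def _params_header(config: RunConfig) -> str:
    return (
        f"paraloglens {__version__}\n"
        f"alignment={config.alignment} isoform_map={config.isoform_map}\n"
        f"ref1={config.ref1} ref2={config.ref2} correction={config.correction}\n"
        f"min_cons={config.min_cons} min_len={config.min_len} "
        f"max_violations={config.max_violations} background={config.background} "
        f"pseudocount={config.pseudocount} model_pi={config.model_pi} "
        f"seed={config.seed}"
    )


def run_pipeline(config: RunConfig, verbose: bool = False) -> Path:
    """Execute the enabled stages; returns the report directory.

    Any stage error aborts the run with the failing stage named in the log
    and in the raised exception.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir, verbose)
    log.info("paraloglens %s starting; output -> %s", __version__, out_dir)
    log.debug("full config: %r", config)

    aln = read_alignment(config.alignment, config.alignment_format)
    raw_map = read_isoform_map(config.isoform_map)
    iso_map = {sid: iso for sid, (_, iso) in raw_map.items()}
    log.info(
        "alignment: %d sequences x %d columns (%d ISO1, %d ISO2)",
        len(aln), aln.n_cols,
        sum(1 for v in iso_map.values() if v is Isoform.ISO1),
        sum(1 for v in iso_map.values() if v is Isoform.ISO2),
    )
    header = _params_header(config)

    profile = None
    stage = None
    try:
        if "conserve" in config.stages:
            stage = "conserve"
            profile = conservation_profile(aln, iso_map, config.ref1, config.ref2)
            profile_to_tsv(profile, out_dir / "profile.tsv", header)
            log.info("conserve: wrote profile.tsv (%d columns)", len(profile))
            if config.domains:
                anns = read_domain_annotations(config.domains)
                summary = domain_identity_summary(profile, anns)
                with open(out_dir / "domain_summary.tsv", "w") as fh:
                    for line in header.splitlines():
                        fh.write(f"# {line}\n")
                    summary.to_csv(fh, sep="\t", index=False, float_format="%.4f")
                log.info("conserve: wrote domain_summary.tsv")
        else:
            log.info("conserve: skipped (stage disabled)")

        if "tree" in config.stages:
            stage = "tree"
            correction = Correction(config.correction.lower())
            subsets = {"joint": list(aln.ids)}
            for iso in (Isoform.ISO1, Isoform.ISO2):
                members = [s for s in aln.ids if iso_map.get(s) is iso]
                if len(members) >= 3:
                    subsets[iso.value.lower()] = members
            for name, members in subsets.items():
                rows = [aln.row(s) for s in members]
                sub = aln if name == "joint" else _subalignment(members, rows)
                dm = distance_matrix(sub, correction)
                tree = me_tree(dm)
                if name == "joint" and config.outgroup:
                    tree = root_tree(tree, set(config.outgroup))
                path = out_dir / ("tree.nwk" if name == "joint" else f"tree_{name}.nwk")
                with open(path, "w") as fh:
                    for line in header.splitlines():
                        fh.write(f"# {line}\n")
                    fh.write(tree.to_newick() + "\n")
                log.info("tree: wrote %s (%d taxa)", path.name, len(dm))
        else:
            log.info("tree: skipped (stage disabled)")

        if "motifs" in config.stages:
            stage = "motifs"
            if profile is None:
                profile = conservation_profile(aln, iso_map, config.ref1, config.ref2)
            calls = call_motifs(
                profile,
                min_cons=config.min_cons,
                min_len=config.min_len,
                max_violations=config.max_violations,
            )
            weights = henikoff_weights(aln)
            if config.background == "empirical":
                from .motifs import empirical_background

                bg = empirical_background(aln)
            else:
                bg = None
            logos = [
                logo_matrix(
                    aln,
                    call.columns,
                    weights=weights,
                    background=bg,
                    pseudocount=config.pseudocount,
                    members=[
                        s for s in aln.ids if iso_map.get(s) is call.isoform
                    ],
                )
                for call in calls
            ]
            motif_report(calls, logos, aln, out_dir, header)
            log.info("motifs: %d calls; wrote motifs.tsv and logo matrices",
                     len(calls))
        else:
            log.info("motifs: skipped (stage disabled)")

        if "ancestral" in config.stages:
            stage = "ancestral"
            correction = Correction(config.correction.lower())
            dm = distance_matrix(aln, correction)
            tree = me_tree(dm)
            outgroup = set(config.outgroup) if config.outgroup else {sorted(aln.ids)[0]}
            rooted = root_tree(tree, outgroup)
            model = (
                SubstitutionModel.empirical(aln)
                if config.model_pi == "empirical"
                else SubstitutionModel.uniform()
            )
            recon = marginal_posteriors(rooted, aln, model)
            write_ancestral_fasta(
                recon, out_dir / "ancestors.fasta", out_dir / "ancestors_posterior.tsv"
            )
            log.info(
                "ancestral: %d internal nodes, total log-likelihood %.3f",
                len(recon.node_names), recon.total_log_likelihood,
            )
        else:
            log.info("ancestral: skipped (stage disabled)")
    except Exception:
        log.exception("stage %r failed; aborting", stage)
        raise
    log.info("done")
    return out_dir


def _subalignment(members: list[str], rows: list[str]):
    from .records import Alignment

    # drop columns that became all-gap after subsetting
    keep = [
        c for c in range(len(rows[0])) if any(r[c] != "-" for r in rows)
    ]
    return Alignment(members, ["".join(r[c] for c in keep) for r in rows])
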