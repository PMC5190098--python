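"""End-to-end scanning of query proteins for predicted hydroxylation sites.

A fitted :class:`~hydsite.classify.SequenceCoupledSiteClassifier` is applied
to every occurrence of the target residue in a query protein; windows are
cut out with the same X-padding as during benchmark construction, so
scanning a protein is byte-identical to extracting its windows and scoring
them.  The self-consistency rule is enforced: a Pro model only scans Pro
residues, a Lys model only Lys.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib

from .classify import SelfConsistencyError, SequenceCoupledSiteClassifier
from .peptides import AnnotatedProtein, ProteinRecord, ValidationError, read_fasta

BUNDLE_FORMAT = "hydsite-bundle-1"


@dataclass(frozen=True)
class SitePrediction:
    """One scored candidate site in a query protein."""

    protein_id: str
    position: int     # 1-based
    residue: str      # P or K
    score: float      # vote fraction in [0, 1]
    predicted: bool


def save_bundle(classifier: SequenceCoupledSiteClassifier, path: str | Path) -> None:
    """Persist a fitted classifier (coupling tables + forest) to one file."""
    if not hasattr(classifier, "forest_"):
        raise ValidationError("cannot save an unfitted classifier")
    joblib.dump({
        "format": BUNDLE_FORMAT,
        "target": classifier.target_,
        "xi": classifier.xi_,
        "params": classifier.get_params(),
        "classifier": classifier,
    }, path)


def load_bundle(path: str | Path) -> SequenceCoupledSiteClassifier:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != BUNDLE_FORMAT:
        raise ValidationError(f"{path} is not a hydsite model bundle")
    return payload["classifier"]


def scan_protein(protein: ProteinRecord,
                 classifier: SequenceCoupledSiteClassifier,
                 threshold: float = 0.5,
                 target: str | None = None) -> list[SitePrediction]:
    """Score every occurrence of the model's target residue in one protein."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    if not hasattr(classifier, "forest_"):
        raise ValidationError("classifier is not fitted")
    if target is not None and target.upper() != classifier.target_:
        raise SelfConsistencyError(
            f"requested target {target!r} but the model was trained for "
            f"{classifier.target_!r} (self-consistency rule)"
        )
    from .peptides import extract_samples

    samples = extract_samples(AnnotatedProtein(protein), classifier.target_,
                              classifier.xi_)
    if not samples:
        return []
    scores = classifier.predict_scores([s.window for s in samples])
    return [
        SitePrediction(
            protein_id=protein.id, position=s.center_position,
            residue=classifier.target_, score=float(score),
            predicted=bool(score >= threshold),
        )
        for s, score in zip(samples, scores)
    ]


def run_batch(fasta_path: str | Path, bundle_path: str | Path,
              target: str | None = None, threshold: float = 0.5,
              output_path: str | Path = "predictions.tsv") -> Path:
    """Scan every protein in a FASTA file and write a TSV report.

    Columns: protein_id, position, residue, score, predicted.  A comment
    line per protein summarizes how many target residues were scanned and
    how many sites were called.  The bundle/target check happens before any
    scanning or output.
    """
    classifier = load_bundle(bundle_path)
    if target is not None and target.upper() != classifier.target_:
        raise SelfConsistencyError(
            f"requested target {target!r} but bundle {bundle_path} was trained "
            f"for {classifier.target_!r}"
        )
    proteins = read_fasta(fasta_path)  # raises on empty input before output
    output_path = Path(output_path)
    with open(output_path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\tscore\tpredicted\n")
        for protein in proteins:
            predictions = scan_protein(protein, classifier, threshold)
            for p in predictions:
                fh.write(f"{p.protein_id}\t{p.position}\t{p.residue}\t"
                         f"{p.score:.6f}\t{int(p.predicted)}\n")
            n_called = sum(p.predicted for p in predictions)
            fh.write(f"# {protein.id}: {len(predictions)} {classifier.target_} "
                     f"residues scanned, {n_called} predicted hydroxylation sites\n")
    return output_path
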