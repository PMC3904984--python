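"""End-to-end driver: classify -> completeness -> retention -> HGT -> stats.

The driver only composes the stage functions — every number in the
report equals what the stages produce when called individually.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import codon_hgt, io, pathway, stats
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    inventory_path: Optional[str] = None
    cds_path: Optional[str] = None
    out_dir: str = "lipoarch_out"
    hgt_alpha_primary: float = 0.10
    hgt_alpha_strict: float = 0.05
    motif_max_mismatch: int = 1
    genetic_code_id: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        for alpha in (self.hgt_alpha_primary, self.hgt_alpha_strict):
            if not 0.0 < alpha < 1.0:
                raise ParameterError("HGT thresholds must lie in (0, 1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all applicable stages, write calls.tsv / hgt.tsv / report.json.

    Partial outputs are removed if any stage fails.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "hgt_alpha_primary": config.hgt_alpha_primary,
            "hgt_alpha_strict": config.hgt_alpha_strict,
            "motif_max_mismatch": config.motif_max_mismatch,
            "genetic_code_id": config.genetic_code_id,
            "seed": config.seed,
        },
    }
    try:
        if config.inventory_path:
            logger.info("[classify] reading inventory %s", config.inventory_path)
            inventories = io.read_inventory(config.inventory_path)
            calls = pathway.call_inventories(inventories)
            calls_path = out_dir / "calls.tsv"
            io.write_calls(calls, calls_path)
            written.append(calls_path)
            summary = pathway.summarize_retention(calls)
            report["retention"] = summary.as_dict()
            logger.info("[stats] concordance over %d species", len(calls))
            try:
                conc = stats.concordance_report(calls)
                report["concordance"] = {
                    "table": [conc.table.a, conc.table.b, conc.table.c, conc.table.d],
                    "chi2_yates": conc.test.statistic,
                    "p_value": conc.test.p_value,
                    "concordance": conc.concordance,
                    "n_indeterminate": conc.n_indeterminate,
                    "n_unknown_phenotype": conc.n_unknown_phenotype,
                }
            except DataError as exc:
                report["concordance"] = {"error": str(exc)}
        if config.cds_path:
            logger.info("[hgt] screening CDS %s", config.cds_path)
            records = io.read_fasta(config.cds_path)
            profile, hgt_calls = codon_hgt.screen_genome(records)
            import pandas as pd

            hgt_path = out_dir / "hgt.tsv"
            pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "p_value": c.p_value,
                        "flagged_p10": c.flagged_p10,
                        "flagged_p05": c.flagged_p05,
                    }
                    for c in hgt_calls
                ]
            ).to_csv(hgt_path, sep="\t", index=False)
            written.append(hgt_path)
            n = len(hgt_calls)
            n10 = sum(c.flagged_p10 for c in hgt_calls)
            report["hgt"] = {
                "n_genes": n,
                "n_flagged_p10": n10,
                "n_flagged_p05": sum(c.flagged_p05 for c in hgt_calls),
                "pct_flagged_p10": 100.0 * n10 / n if n else 0.0,
                "profile_converged": profile.converged,
                "profile_iterations": profile.n_iterations,
            }
        if "retention" not in report and "hgt" not in report:
            raise ParameterError("pipeline needs an inventory and/or a CDS FASTA")
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(report_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return report
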