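"""Curation rules: loading, thresholds, region pruning, allele referencing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transrep.replication_db import (
    ValidationError,
    apply_discovery_filters,
    load_tables,
    reference_risk_allele,
    select_attempts,
)
from transrep.synthetic_data import DbSimConfig, gen_replication_database, \
    write_database


def brute_force_filter(assoc, studies, p_geno=5e-7, p_imp=5e-8):
    """Independent oracle: O(n^2) pairwise chaining and explicit rules."""
    imp = dict(zip(studies["study_id"], studies["uses_imputation"]))
    rows = []
    for _, row in assoc.iterrows():
        if row["sex_specific"]:
            continue
        thr = p_imp if imp[row["discovery_study_id"]] else p_geno
        if row["p_discovery"] >= thr:
            continue
        if str(row["chrom"]) == "6" and 25e6 <= row["pos_bp"] <= 35e6:
            continue
        rows.append(row)
    kept = pd.DataFrame(rows)
    if kept.empty:
        return set()
    survivors = set()
    for (disease, chrom), grp in kept.groupby(["disease", "chrom"]):
        grp = grp.sort_values("pos_bp")
        # transitive chaining: union-find over pairs < 200 kb apart
        idx = list(grp.index)
        parent = {i: i for i in idx}

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in idx:
            for j in idx:
                if i < j and abs(grp.loc[i, "pos_bp"] - grp.loc[j, "pos_bp"]) \
                        < 200_000:
                    parent[find(j)] = find(i)
        clusters = {}
        for i in idx:
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            sub = grp.loc[members].sort_values(["p_discovery", "pos_bp"])
            survivors.add(sub.iloc[0]["snp_id"])
    return survivors


def make_tables(assoc_rows, uses_imputation=False):
    studies = pd.DataFrame([{
        "study_id": "S1", "disease": "d", "ancestry": "European",
        "year": 2010, "n_gwas_stage": 5000, "n_replication_stage": 5000,
        "uses_imputation": uses_imputation, "genomic_control_lambda": 1.0,
    }])
    defaults = dict(disease="d", discovery_study_id="S1", risk_allele="A",
                    other_allele="G", or_discovery=1.2, log_or=np.log(1.2),
                    maf_discovery_pop=0.3, sex_specific=False,
                    region_id=None)
    assoc = pd.DataFrame([{**defaults, **row} for row in assoc_rows])
    return assoc, studies


class TestLoadTables:
    def test_synthetic_round_trip(self, small_db, tmp_path):
        paths = write_database(small_db, tmp_path)
        tables = load_tables(paths["studies"], paths["associations"],
                             paths["attempts"])
        assert len(tables.attempts) == len(small_db.attempts)
        assert len(tables.associations) == len(small_db.associations)

    def test_dangling_snp_reference_names_it(self, small_db, tmp_path):
        broken = small_db.attempts.copy()
        broken.loc[broken.index[0], "snp_id"] = "rs_nowhere"
        paths = write_database(small_db, tmp_path)
        broken.to_csv(tmp_path / "attempts.tsv", sep="\t", index=False,
                      na_rep=".")
        with pytest.raises(ValidationError, match="rs_nowhere"):
            load_tables(paths["studies"], paths["associations"],
                        tmp_path / "attempts.tsv")

    def test_decimal_comma_is_rejected(self, small_db, tmp_path):
        paths = write_database(small_db, tmp_path)
        text = open(paths["attempts"]).read().splitlines()
        header = text[1].split("\t")
        col = header.index("or_replication")
        fields = text[2].split("\t")
        fields[col] = "1,23"
        text[2] = "\t".join(fields)
        (tmp_path / "attempts.tsv").write_text("\n".join(text) + "\n")
        with pytest.raises(ValidationError, match="or_replication"):
            load_tables(paths["studies"], paths["associations"],
                        tmp_path / "attempts.tsv")


class TestDiscoveryFilters:
    def test_imputation_toughens_threshold(self):
        row = dict(snp_id="rs1", chrom="1", pos_bp=1_000_000,
                   p_discovery=2e-7)
        for imputed, expect_kept in [(False, True), (True, False)]:
            assoc, studies = make_tables([row], uses_imputation=imputed)
            kept, log = apply_discovery_filters(assoc, studies)
            assert (len(kept) == 1) is expect_kept
            if not expect_kept:
                assert log.iloc[0]["reason"] == "p_above_threshold"

    def test_prune_keeps_lowest_p_within_200kb(self):
        assoc, studies = make_tables([
            dict(snp_id="rs1", chrom="1", pos_bp=100_000, p_discovery=1e-8),
            dict(snp_id="rs2", chrom="1", pos_bp=250_000, p_discovery=1e-9),
        ])
        kept, log = apply_discovery_filters(assoc, studies)
        assert list(kept["snp_id"]) == ["rs2"]
        assert dict(zip(log["snp_id"], log["reason"]))["rs1"] == \
            "not_min_p_in_region"

    def test_exactly_200kb_plus_one_is_two_regions(self):
        assoc, studies = make_tables([
            dict(snp_id="rs1", chrom="1", pos_bp=100_000, p_discovery=1e-8),
            dict(snp_id="rs2", chrom="1", pos_bp=300_001, p_discovery=1e-9),
        ])
        kept, _ = apply_discovery_filters(assoc, studies)
        assert sorted(kept["snp_id"]) == ["rs1", "rs2"]
        assert kept["region_id"].nunique() == 2

    def test_mhc_and_sex_specific_dropped(self):
        assoc, studies = make_tables([
            dict(snp_id="rs_mhc", chrom="6", pos_bp=30_000_000,
                 p_discovery=1e-10),
            dict(snp_id="rs_sex", chrom="2", pos_bp=1_000_000,
                 p_discovery=1e-10, sex_specific=True),
            dict(snp_id="rs_ok", chrom="2", pos_bp=5_000_000,
                 p_discovery=1e-10),
        ])
        kept, log = apply_discovery_filters(assoc, studies)
        assert list(kept["snp_id"]) == ["rs_ok"]
        reasons = dict(zip(log["snp_id"], log["reason"]))
        assert reasons == {"rs_mhc": "mhc_region", "rs_sex": "sex_specific"}

    def test_matches_brute_force_oracle_on_random_toy_table(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(20):
            rows.append(dict(
                snp_id=f"rs{i}",
                chrom=str(rng.choice(["1", "1", "6", "2"])),
                pos_bp=int(rng.integers(1, 40_000_000)),
                p_discovery=float(10.0 ** rng.uniform(-12, -5)),
                sex_specific=bool(rng.random() < 0.15),
            ))
        assoc, studies = make_tables(rows, uses_imputation=True)
        # de-duplicate positions so ordering is unambiguous
        assoc = assoc.drop_duplicates(subset=["chrom", "pos_bp"])
        kept, _ = apply_discovery_filters(assoc, studies)
        assert set(kept["snp_id"]) == brute_force_filter(assoc, studies)

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(17)
        rows = [dict(snp_id=f"rs{i}", chrom=str(rng.choice(["1", "3"])),
                     pos_bp=int(rng.integers(1, 10_000_000)),
                     p_discovery=float(10.0 ** rng.uniform(-12, -6)))
                for i in range(15)]
        assoc, studies = make_tables(rows)
        once, _ = apply_discovery_filters(assoc, studies)
        twice, _ = apply_discovery_filters(once, studies)
        pd.testing.assert_frame_equal(once, twice)


class TestRiskAlleleReferencing:
    def test_opposite_allele_inverts_or(self):
        result = reference_risk_allele(2.0, "G", "A")
        assert result.or_value == pytest.approx(0.5)
        assert result.shift is True

    def test_or_one_has_undefined_direction(self):
        result = reference_risk_allele(1.0, "A", "A")
        assert result.log_or == 0.0
        assert result.direction_same is None

    def test_same_allele_is_noop(self):
        result = reference_risk_allele(1.25, "A", "A")
        assert result.or_value == pytest.approx(1.25)
        assert result.shift is False
        assert result.log_or == pytest.approx(np.log(1.25))

    def test_shift_is_an_involution(self):
        once = reference_risk_allele(1.7, "G", "A")
        back = reference_risk_allele(once.or_value, "G", "A")
        assert back.or_value == pytest.approx(1.7)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=1e-3, max_value=1e3,
                     allow_nan=False, allow_infinity=False))
    def test_shift_involution_property(self, or_value):
        once = reference_risk_allele(or_value, "G", "A")
        back = reference_risk_allele(once.or_value, "G", "A")
        assert once.shift and back.shift
        assert back.or_value == pytest.approx(or_value, rel=1e-12)
        assert once.log_or == pytest.approx(-back.log_or, abs=1e-12)

    def test_nonpositive_or_raises(self):
        with pytest.raises(ValueError):
            reference_risk_allele(0.0, "A", "A")


class TestSelectAttempts:
    def test_all_is_identity(self, toy_attempts):
        pd.testing.assert_frame_equal(
            select_attempts(toy_attempts, "all"), toy_attempts)

    def test_largest_per_snp_keeps_biggest_sample(self):
        frame = pd.DataFrame({
            "snp_id": ["rs1", "rs1"],
            "replication_study_id": ["A", "B"],
            "n_cases": [500, 2500], "n_controls": [500, 2500],
            "power": [0.5, 0.9],
        })
        out = select_attempts(frame, "largest_per_snp")
        assert list(out["replication_study_id"]) == ["B"]

    def test_one_row_per_snp_matches_groupby_oracle(self, small_db):
        attempts = small_db.attempts
        out = select_attempts(attempts, "largest_per_snp")
        assert len(out) == attempts["snp_id"].nunique()
        # brute-force group-by oracle
        oracle = (
            attempts.assign(n=attempts.n_cases + attempts.n_controls)
            .sort_values(["n", "replication_study_id"],
                         ascending=[False, True], kind="stable")
            .drop_duplicates("snp_id")
        )
        assert set(out["replication_study_id"]) == \
            set(oracle["replication_study_id"])

    def test_most_powered_requires_power(self, toy_attempts):
        missing = toy_attempts.assign(power=np.nan)
        with pytest.raises(ValueError, match="power"):
            select_attempts(missing, "most_powered_per_snp")
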