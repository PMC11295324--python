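import dataclasses

import numpy as np
import pytest

from qdl.store import (
    StoreEntry,
    StoreIndex,
    SVDFactors,
    choose_rank,
    ingest,
    load_factors,
    parse_entry_payload,
    retrieve,
    save_factors,
    similarity,
    svd_compress,
    svd_reconstruct,
)
from qdl.synth import PhantomSpec, generate_metadata_record, generate_phantom_image, save_image_png


def _record(tmp_path, image, key, seed=0):
    path = tmp_path / f"{key}.png"
    save_image_png(image, path)
    record = generate_metadata_record(seed, path)
    return dataclasses.replace(record, record_id=key)


class TestSVD:
    def test_rank_one_outer_product_exact(self):
        u = np.linspace(0.1, 1.0, 12)
        v = np.linspace(1.0, 0.2, 9)
        A = np.clip(np.outer(u, v), 0, 1)
        f = svd_compress(A, rank=1)
        np.testing.assert_allclose(svd_reconstruct(f), A, atol=1e-10)

    def test_identity_rank2_error_one(self):
        f = svd_compress(np.eye(3), rank=2)
        err = ((svd_reconstruct(f, clip=False) - np.eye(3)) ** 2).sum()
        assert abs(err - 1.0) < 1e-10

    def test_eckart_young_equality(self, rng):
        for _ in range(10):
            A = rng.random((16, 12))
            s_all = np.linalg.svd(A, compute_uv=False)
            for rank in range(1, 13):
                f = svd_compress(A, rank)
                err = ((svd_reconstruct(f, clip=False) - A) ** 2).sum()
                tail = (s_all[rank:] ** 2).sum()
                assert err == pytest.approx(tail, rel=1e-8, abs=1e-10)

    def test_error_nonincreasing_in_rank(self, rng):
        A = rng.random((32, 32))
        errors = [
            ((svd_reconstruct(svd_compress(A, r), clip=False) - A) ** 2).sum() for r in range(1, 33)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(errors, errors[1:]))

    def test_full_rank_lossless(self, rng):
        A = rng.random((10, 8))
        np.testing.assert_allclose(svd_reconstruct(svd_compress(A, 8), clip=False), A, atol=1e-8)

    def test_clipping_never_hurts(self, rng):
        A = rng.random((12, 12))
        f = svd_compress(A, 3)
        raw = svd_reconstruct(f, clip=False)
        clipped = svd_reconstruct(f, clip=True)
        assert ((clipped - A) ** 2).sum() <= ((raw - A) ** 2).sum() + 1e-12

    def test_tall_matrix_qr_path(self, rng):
        A = rng.random((64, 8))
        f = svd_compress(A, 4)
        s_all = np.linalg.svd(A, compute_uv=False)
        err = ((svd_reconstruct(f, clip=False) - A) ** 2).sum()
        assert err == pytest.approx((s_all[4:] ** 2).sum(), rel=1e-8)

    def test_rank_validation(self):
        with pytest.raises(ValueError):
            svd_compress(np.eye(4), 5)
        with pytest.raises(ValueError):
            svd_compress(np.eye(4), 0)

    def test_orthonormal_factors(self, rng):
        f = svd_compress(rng.random((20, 15)), 6)
        np.testing.assert_allclose(f.U.T @ f.U, np.eye(6), atol=1e-8)
        np.testing.assert_allclose(f.Vt @ f.Vt.T, np.eye(6), atol=1e-8)


class TestChooseRank:
    def test_full_energy_full_rank(self):
        assert choose_rank([3.0, 2.0, 1.0], 1.0) == 3

    def test_hand_case(self):
        assert choose_rank([2.0, 1.0, 1.0], 0.5) == 1  # 4/6 >= 0.5

    def test_monotone_in_fraction(self, rng):
        s = np.sort(rng.random(10))[::-1]
        ranks = [choose_rank(s, f) for f in np.linspace(0.05, 1.0, 20)]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            choose_rank([], 0.5)
        with pytest.raises(ValueError):
            choose_rank([1.0], 1.5)


class TestSimilarity:
    def test_identical_is_one(self):
        assert similarity([0.3, 0.7], [0.3, 0.7]) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_hand_value(self):
        # sum sqrt(ab) = sqrt(0.45) + sqrt(0.05) computed by hand
        expected = np.sqrt(0.45) + np.sqrt(0.05)
        assert similarity([0.5, 0.5], [0.9, 0.1]) == pytest.approx(expected, abs=1e-12)
        assert similarity([0.5, 0.5], [0.9, 0.1]) == pytest.approx(0.89443, abs=5e-6)


class TestStoreEntryInvariants:
    def test_exactly_one_of_factors_or_tag(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=0))
        record = _record(tmp_path, img, "K1")
        with pytest.raises(ValueError):
            StoreEntry(key="K1", record=record, qr_payload="x")

    def test_tag_requires_high_similarity(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=0))
        record = _record(tmp_path, img, "K1")
        with pytest.raises(ValueError):
            StoreEntry(key="K1", record=record, qr_payload="x", tag_ref="K0", similarity=0.5)


class TestIngestRetrieve:
    def test_duplicate_image_becomes_tag(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=1))
        store = StoreIndex()
        e1 = ingest(_record(tmp_path, img, "A"), img, store)
        e2 = ingest(_record(tmp_path, img, "B"), img, store)
        assert not e1.is_tag
        assert e2.is_tag and e2.tag_ref == "A"
        assert e2.similarity == pytest.approx(1.0)

    def test_first_entry_always_full(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=2))
        store = StoreIndex()
        assert not ingest(_record(tmp_path, img, "A"), img, store).is_tag

    def test_disjoint_feature_images_both_full(self, tmp_path, monkeypatch):
        import qdl.store as store_mod

        # feature distributions with disjoint support -> similarity 0
        fake = {0: np.array([1.0, 0.0]), 1: np.array([0.0, 1.0])}
        calls = iter([0, 1])
        monkeypatch.setattr(store_mod, "image_distribution", lambda img: fake[next(calls)])
        img, _ = generate_phantom_image(PhantomSpec(seed=3))
        store = StoreIndex()
        e1 = ingest(_record(tmp_path, img, "A"), img, store)
        e2 = ingest(_record(tmp_path, img, "B"), img, store)
        assert not e1.is_tag and not e2.is_tag

    def test_duplicate_key_rejected(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=4))
        store = StoreIndex()
        record = _record(tmp_path, img, "A")
        ingest(record, img, store)
        with pytest.raises(KeyError):
            ingest(record, img, store)

    def test_retrieve_roundtrip_all_12_fields(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=5))
        store = StoreIndex(tmp_path / "store")
        record = _record(tmp_path, img, "A")
        ingest(record, img, store, energy_fraction=1.0)
        got, recon = retrieve(store, "A")
        assert got.to_dict() == record.to_dict()
        assert recon.shape == img.shape
        # full-rank request keeps reconstruction near-lossless
        assert np.abs(recon - img).max() < 1e-6

    def test_retrieve_via_qr_equals_retrieve_via_key(self, tmp_path):
        from qdl.synth import load_image_png

        img, _ = generate_phantom_image(PhantomSpec(seed=6))
        store = StoreIndex(tmp_path / "store")
        record = _record(tmp_path, img, "A")
        entry = ingest(record, img, store)
        by_key = retrieve(store, "A")
        by_qr = retrieve(store, load_image_png(entry.qr_image_ref))
        assert by_key[0] == by_qr[0]
        np.testing.assert_array_equal(by_key[1], by_qr[1])

    def test_tagged_entry_returns_reference_reconstruction(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=7))
        store = StoreIndex()
        ingest(_record(tmp_path, img, "A"), img, store)
        ingest(_record(tmp_path, img, "B"), img, store)
        rec_a, recon_a = retrieve(store, "A")
        rec_b, recon_b = retrieve(store, "B")
        np.testing.assert_array_equal(recon_a, recon_b)
        assert rec_b.record_id == "B"

    def test_no_tag_chains_randomized(self, tmp_path):
        rng = np.random.default_rng(0)
        base_images = [generate_phantom_image(PhantomSpec(seed=s))[0] for s in range(4)]
        store = StoreIndex()
        for i in range(60):
            img = base_images[int(rng.integers(4))]
            if rng.random() < 0.3:  # jitter some copies
                img = np.clip(img + rng.normal(0, 0.01, img.shape), 0, 1)
            ingest(_record(tmp_path, img, f"K{i:03d}", seed=i), img, store)
        for entry in store.entries.values():
            if entry.is_tag:
                target = store.entries[entry.tag_ref]
                assert not target.is_tag
                assert entry.similarity > 0.70

    def test_threshold_monotonicity(self, tmp_path):
        rng = np.random.default_rng(1)
        images = []
        for s in range(12):
            img, _ = generate_phantom_image(PhantomSpec(seed=s % 3))
            images.append(np.clip(img + rng.normal(0, 0.02, img.shape), 0, 1))
        counts = []
        for threshold in (0.5, 0.7, 0.9, 0.99):
            store = StoreIndex()
            for i, img in enumerate(images):
                ingest(_record(tmp_path, img, f"K{i}", seed=i), img, store, threshold=threshold)
            counts.append(sum(1 for e in store.entries.values() if not e.is_tag))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_dedup_disabled_all_full(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=8))
        store = StoreIndex()
        ingest(_record(tmp_path, img, "A"), img, store, dedup=False)
        e2 = ingest(_record(tmp_path, img, "B"), img, store, dedup=False)
        assert not e2.is_tag

    def test_unknown_key(self):
        with pytest.raises(KeyError):
            retrieve(StoreIndex(), "nope")


class TestPersistence:
    def test_factor_file_roundtrip(self, tmp_path, rng):
        f = svd_compress(rng.random((24, 18)), 5)
        path = tmp_path / "f.bin"
        save_factors(f, path)
        g = load_factors(path)
        np.testing.assert_array_equal(g.U, f.U)
        np.testing.assert_array_equal(g.s, f.s)
        np.testing.assert_array_equal(g.Vt, f.Vt)
        assert g.shape == f.shape and g.rank == f.rank

    def test_store_reload(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=9))
        store = StoreIndex(tmp_path / "store")
        record = _record(tmp_path, img, "A")
        ingest(record, img, store)
        ingest(_record(tmp_path, img, "B"), img, store)
        reloaded = StoreIndex.load(tmp_path / "store")
        assert sorted(reloaded.entries) == ["A", "B"]
        assert reloaded.entries["B"].is_tag
        got, _ = retrieve(reloaded, "B")
        assert got.record_id == "B"

    def test_payload_parse_roundtrip(self, tmp_path):
        img, _ = generate_phantom_image(PhantomSpec(seed=10))
        store = StoreIndex()
        entry = ingest(_record(tmp_path, img, "A"), img, store)
        kind, fields = parse_entry_payload(entry.qr_payload)
        assert kind == "full"
        assert fields["key"] == "A"
        assert fields["record_id"] == "A"
        assert "rank" in fields and "shape" in fields
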