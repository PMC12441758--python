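import numpy as np
import pytest

from clusterscape import PointCloud, cluster_dbscan
from clusterscape.synthetic import BlobSpec, make_blobs3d, make_gene_table, make_trajectory


@pytest.fixture(scope="session")
def three_blob_cloud():
    """The standard 3-blob fixture: tight, well-separated Gaussian clusters."""
    return make_blobs3d(BlobSpec(k=3, points_per_cluster=200, center_spread=10.0,
                                 cluster_sd=0.3, seed=42))


@pytest.fixture(scope="session")
def blob_labels(three_blob_cloud):
    cloud, _ = three_blob_cloud
    return cluster_dbscan(cloud)


@pytest.fixture(scope="session")
def planted_gene_table():
    return make_gene_table(n_genes=1000, n_conditions=4, n_significant=250, seed=11)


@pytest.fixture(scope="session")
def small_trajectory(three_blob_cloud):
    cloud, _ = three_blob_cloud
    small = PointCloud(ids=cloud.ids[:100].copy(), coords=cloud.coords[:100].copy())
    return make_trajectory(small, n_snapshots=5, seed=5)


@pytest.fixture
def random_cloud():
    rng = np.random.default_rng(314)
    ids = np.array([f"g{i}" for i in range(80)], dtype=object)
    return PointCloud(ids=ids, coords=rng.normal(scale=8.0, size=(80, 3)))
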