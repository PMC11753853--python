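"""Q2/Q1 (Taylor–Hood) finite-element kernels on axis-aligned quad/hex meshes.

Internal module.  The velocity space is continuous tensor-product quadratic
(Q2), the pressure space continuous bilinear/trilinear (Q1); the pairing is
inf-sup stable, so no pressure stabilization is needed.  All cells are
axis-aligned boxes, which makes the Jacobian diagonal and constant per cell
and allows fully vectorized assembly.

Local tensor ordering everywhere: x fastest, then y (3D), then z.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .meshing import TaggedMesh

_GAUSS_X = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GAUSS_W = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def _shape_q2_1d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    n = np.stack([x * (x - 1) / 2, 1 - x * x, x * (x + 1) / 2], axis=-1)
    d = np.stack([x - 0.5, -2 * x, x + 0.5], axis=-1)
    return n, d


def _shape_q1_1d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    n = np.stack([(1 - x) / 2, (1 + x) / 2], axis=-1)
    d = np.stack([np.full_like(x, -0.5), np.full_like(x, 0.5)], axis=-1)
    return n, d


def _tensor_basis(dim: int, pts_1d: np.ndarray, order: int):
    """Tensor-product shapes at tensor-product points.

    Returns (points (nq, dim), PHI (nq, nb), DPHI (nq, nb, dim)) in
    reference coordinates on [-1, 1]^dim.
    """
    shape_1d = _shape_q2_1d if order == 2 else _shape_q1_1d
    n1, d1 = shape_1d(pts_1d)            # (np1, k)
    k = n1.shape[-1]
    grids = np.meshgrid(*([np.arange(len(pts_1d))] * dim), indexing="ij")
    # x fastest: iterate with x as the last meshgrid axis reversed ordering
    qidx = np.stack([g.ravel(order="F") for g in grids], axis=1)  # (nq, dim)
    pts = pts_1d[qidx]
    bidx = np.stack(
        [g.ravel(order="F") for g in np.meshgrid(*([np.arange(k)] * dim), indexing="ij")],
        axis=1,
    )  # (nb, dim)
    nq, nb = len(qidx), len(bidx)
    phi = np.ones((nq, nb))
    dphi = np.ones((nq, nb, dim))
    for d in range(dim):
        nd = n1[qidx[:, d]][:, None, bidx[:, d]][:, 0, :]   # (nq, nb)
        dd = d1[qidx[:, d]][:, None, bidx[:, d]][:, 0, :]
        phi = phi * nd
        for e in range(dim):
            dphi[:, :, e] *= dd if e == d else nd
    return pts, phi, dphi


def _quad_weights(dim: int) -> np.ndarray:
    w = _GAUSS_W
    out = w
    for _ in range(dim - 1):
        out = np.multiply.outer(w, out).ravel(order="F")
    return out


def _q2_local_corner_subsets(dim: int) -> list[np.ndarray]:
    """For each local Q2 node, the cell-corner locals it is the midpoint of."""
    k = 3
    bidx = np.stack(
        [g.ravel(order="F") for g in np.meshgrid(*([np.arange(k)] * dim), indexing="ij")],
        axis=1,
    )
    subsets = []
    for a in bidx:
        choices = [[c // 2] if c in (0, 2) else [0, 1] for c in a]
        locs = []
        grids = np.meshgrid(*choices, indexing="ij")
        for combo in zip(*[g.ravel() for g in grids]):
            locs.append(sum(combo[d] << d for d in range(dim)))
        subsets.append(np.array(sorted(locs)))
    return subsets


def _face_q2_locals(dim: int) -> dict[int, np.ndarray]:
    """Local Q2 indices lying on each face, tensor-ordered over in-plane axes."""
    k = 3
    bidx = np.stack(
        [g.ravel(order="F") for g in np.meshgrid(*([np.arange(k)] * dim), indexing="ij")],
        axis=1,
    )
    out = {}
    for face in range(2 * dim):
        d, side = face // 2, face % 2
        val = 0 if side == 0 else 2
        mask = bidx[:, d] == val
        locs = np.flatnonzero(mask)
        inplane = [e for e in range(dim) if e != d]
        key = np.zeros(len(locs))
        for rank, e in enumerate(inplane):
            key += bidx[locs, e] * (k ** rank)
        out[face] = locs[np.argsort(key)]
    return out


class Q2Q1Space:
    """Velocity/pressure dof management and assembly for one mesh."""

    def __init__(self, mesh: TaggedMesh):
        self.mesh = mesh
        self.dim = mesh.dim
        dim = self.dim
        cells = mesh.cells
        nv = mesh.n_nodes

        subsets = _q2_local_corner_subsets(dim)
        nb2 = len(subsets)
        cell_q2 = np.empty((len(cells), nb2), dtype=np.int64)
        coords = [mesh.nodes]
        offset = nv
        # group local nodes by the number of corners they average
        by_len: dict[int, list[int]] = {}
        for a, s in enumerate(subsets):
            by_len.setdefault(len(s), []).append(a)
        for a in by_len.get(1, []):
            cell_q2[:, a] = cells[:, subsets[a][0]]
        for m in (2, 4, 8):
            locs = by_len.get(m, [])
            if not locs:
                continue
            keys = np.concatenate(
                [np.sort(cells[:, subsets[a]], axis=1) for a in locs], axis=0
            )
            uniq, inv = np.unique(keys, axis=0, return_inverse=True)
            ids = inv.reshape(len(locs), len(cells)) + offset
            for i, a in enumerate(locs):
                cell_q2[:, a] = ids[i]
            coords.append(mesh.nodes[uniq].mean(axis=1))
            offset += len(uniq)
        self.cell_q2 = cell_q2
        self.q2_coords = np.concatenate(coords, axis=0)
        self.n_q2 = offset
        self.n_p = nv
        self.n_dofs = dim * self.n_q2 + self.n_p

        # volume quadrature reference data
        _, self.phi2, self.dphi2 = _tensor_basis(dim, _GAUSS_X, 2)
        _, self.phi1, self.dphi1 = _tensor_basis(dim, _GAUSS_X, 1)
        self.wq = _quad_weights(dim)
        self.detJ = mesh.cell_sizes.prod(axis=1) / 2.0 ** dim
        self.inv_h = 2.0 / mesh.cell_sizes  # (Nc, dim)

        # facet reference data (dim-1 tensor elements)
        self.face_locals = _face_q2_locals(dim)
        if dim == 2:
            self.fphi2 = _shape_q2_1d(_GAUSS_X)[0]
            self.fwq = _GAUSS_W
        else:
            _, self.fphi2, _ = _tensor_basis(2, _GAUSS_X, 2)
            self.fwq = _quad_weights(2)
        # face-center Q2 gradient table per face
        self.face_center_dphi = {}
        for face in range(2 * dim):
            d, side = face // 2, face % 2
            pt = np.zeros((1, dim))
            pt[0, d] = -1.0 if side == 0 else 1.0
            pts1 = pt[0]
            _, _, dphi = _tensor_basis_at(dim, pts1)
            self.face_center_dphi[face] = dphi[0]  # (nb2, dim)

    # ------------------------------------------------------------------
    def velocity_dof(self, component: int) -> slice:
        return slice(component * self.n_q2, (component + 1) * self.n_q2)

    @property
    def pressure_dof(self) -> slice:
        return slice(self.dim * self.n_q2, self.n_dofs)

    def facet_q2(self, facet_ids: np.ndarray) -> np.ndarray:
        m = self.mesh
        out = np.empty((len(facet_ids), len(self.face_locals[0])), dtype=np.int64)
        for face, locs in self.face_locals.items():
            sel = m.facet_face[facet_ids] == face
            out[sel] = self.cell_q2[m.facet_cell[facet_ids[sel]]][:, locs]
        return out

    def boundary_q2_nodes(self, tags: list[str]) -> np.ndarray:
        ids = np.concatenate(
            [self.mesh.facets_with_tag(t) for t in tags]
        ) if tags else np.array([], dtype=np.int64)
        if len(ids) == 0:
            return np.array([], dtype=np.int64)
        return np.unique(self.facet_q2(ids))

    # -- assembly -------------------------------------------------------
    def _cell_dphi(self, chunk: np.ndarray) -> np.ndarray:
        """(nc, nq, nb2, dim) physical Q2 gradients for a chunk of cells."""
        return self.dphi2[None] * self.inv_h[chunk][:, None, None, :]

    def assemble_laplacian(self, chunk_size: int = 4000) -> sp.csr_matrix:
        """Scalar Q2 stiffness ∫ ∇φ_a · ∇φ_b."""
        nb = self.phi2.shape[1]
        rows, cols, vals = [], [], []
        for chunk in _chunks(len(self.mesh.cells), chunk_size):
            dphi = self._cell_dphi(chunk)
            k = np.einsum("q,cqad,cqbd->cab", self.wq, dphi, dphi, optimize=True)
            k *= self.detJ[chunk][:, None, None]
            conn = self.cell_q2[chunk]
            rows.append(np.repeat(conn, nb, axis=1).ravel())
            cols.append(np.tile(conn, (1, nb)).ravel())
            vals.append(k.ravel())
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_q2, self.n_q2),
        )
        return K.tocsr()

    def assemble_grad_outer(self, chunk_size: int = 4000):
        """G[e][d] with G[e][d][a,b] = ∫ (∂φ_a/∂x_e)(∂φ_b/∂x_d).

        The symmetric-gradient (full viscous stress) momentum blocks are
        A[d][e] = μ(δ_de Σ_f G[f][f] + G[e][d]).
        """
        dim = self.dim
        nb = self.phi2.shape[1]
        vals = [[[] for _ in range(dim)] for _ in range(dim)]
        rows_all, cols_all = [], []
        for chunk in _chunks(len(self.mesh.cells), chunk_size):
            dphi = self._cell_dphi(chunk)
            conn = self.cell_q2[chunk]
            rows_all.append(np.repeat(conn, nb, axis=1).ravel())
            cols_all.append(np.tile(conn, (1, nb)).ravel())
            g = np.einsum("q,cqae,cqbd->cabed", self.wq, dphi, dphi, optimize=True)
            g *= self.detJ[chunk][:, None, None, None, None]
            for e in range(dim):
                for d in range(dim):
                    vals[e][d].append(g[:, :, :, e, d].ravel())
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        shape = (self.n_q2, self.n_q2)
        return [
            [sp.coo_matrix((np.concatenate(vals[e][d]), (rows, cols)), shape).tocsr()
             for d in range(dim)]
            for e in range(dim)
        ]

    def assemble_divergence(self, chunk_size: int = 4000) -> list[sp.csr_matrix]:
        """B_d with (B_d)[p_a, v_b] = ∫ ψ_a ∂φ_b/∂x_d, one matrix per d."""
        nb1, nb2 = self.phi1.shape[1], self.phi2.shape[1]
        mats = []
        for d in range(self.dim):
            rows, cols, vals = [], [], []
            for chunk in _chunks(len(self.mesh.cells), chunk_size):
                dphi = self._cell_dphi(chunk)[:, :, :, d]
                b = np.einsum("q,qa,cqb->cab", self.wq, self.phi1, dphi, optimize=True)
                b *= self.detJ[chunk][:, None, None]
                connp = self.mesh.cells[chunk]
                connv = self.cell_q2[chunk]
                rows.append(np.repeat(connp, nb2, axis=1).ravel())
                cols.append(np.tile(connv, (1, nb1)).ravel())
                vals.append(b.ravel())
            B = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.n_p, self.n_q2),
            )
            mats.append(B.tocsr())
        return mats

    def interpolate_velocity(self, U: np.ndarray, chunk: np.ndarray):
        """Velocity and gradient at volume quadrature points for cells ``chunk``.

        Returns u (nc, nq, dim) and grad (nc, nq, dim, dim) with
        grad[..., d, e] = ∂u_d/∂x_e.
        """
        conn = self.cell_q2[chunk]
        Uc = U[conn]                                   # (nc, nb, dim)
        u = np.einsum("qa,cad->cqd", self.phi2, Uc, optimize=True)
        dphi = self._cell_dphi(chunk)                   # (nc, nq, nb, dim)
        grad = np.einsum("cqae,cad->cqde", dphi, Uc, optimize=True)
        return u, grad

    def assemble_convection(self, U: np.ndarray, chunk_size: int = 1500):
        """Newton linearization of (u·∇)u.

        Returns (C_diag, C_blocks, R) where C_diag is shared by every
        diagonal velocity block, C_blocks[d][e] couples component d (rows)
        to e (cols), and R (n_q2, dim) is the nonlinear residual vector.
        """
        dim = self.dim
        nb = self.phi2.shape[1]
        rows_all, cols_all = [], []
        v_diag = []
        v_blk = [[[] for _ in range(dim)] for _ in range(dim)]
        R = np.zeros((self.n_q2, dim))
        for chunk in _chunks(len(self.mesh.cells), chunk_size):
            u, grad = self.interpolate_velocity(U, chunk)
            dphi = self._cell_dphi(chunk)
            wdet = self.wq[None, :] * self.detJ[chunk][:, None]     # (nc, nq)
            udg = np.einsum("cqe,cqbe->cqb", u, dphi, optimize=True)  # (u·∇)φ_b
            cdiag = np.einsum("cq,qa,cqb->cab", wdet, self.phi2, udg, optimize=True)
            conn = self.cell_q2[chunk]
            rows = np.repeat(conn, nb, axis=1).ravel()
            cols = np.tile(conn, (1, nb)).ravel()
            rows_all.append(rows)
            cols_all.append(cols)
            v_diag.append(cdiag.ravel())
            # reaction part φ_b ∂u_d/∂x_e
            blk = np.einsum(
                "cq,qa,qb,cqde->cabde", wdet, self.phi2, self.phi2, grad, optimize=True
            )
            for d in range(dim):
                for e in range(dim):
                    v_blk[d][e].append(blk[:, :, :, d, e].ravel())
            # residual
            conv = np.einsum("cqde,cqe->cqd", grad, u, optimize=True)
            r = np.einsum("cq,qa,cqd->cad", wdet, self.phi2, conv, optimize=True)
            np.add.at(R, conn.ravel(), r.reshape(-1, dim))
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        shape = (self.n_q2, self.n_q2)
        C_diag = sp.coo_matrix((np.concatenate(v_diag), (rows, cols)), shape).tocsr()
        C_blocks = [
            [
                sp.coo_matrix((np.concatenate(v_blk[d][e]), (rows, cols)), shape).tocsr()
                for e in range(dim)
            ]
            for d in range(dim)
        ]
        return C_diag, C_blocks, R

    def assemble_supg(self, U: np.ndarray, P: np.ndarray, nu: float,
                      chunk_size: int = 1500):
        """Streamline (SUPG) stabilization for convection-dominated cells.

        Test modification w_a = τ (u·∇)φ_a applied to the strong advective
        residual (u·∇)u + ∇p/ρ.  Viscous second derivatives are dropped, as
        is standard for smooth elements.  Returns (S_diag, S_p, R_s) with
        S_p[d] the velocity(d)-row/pressure-column coupling and R_s the
        residual contribution (n_q2, dim) plus pressure part folded in.
        """
        dim = self.dim
        nb, nb1 = self.phi2.shape[1], self.phi1.shape[1]
        h_min = self.mesh.cell_sizes.min(axis=1)
        rows_all, cols_all, v_diag = [], [], []
        rows_p, cols_p = [], []
        v_p = [[] for _ in range(dim)]
        R = np.zeros((self.n_q2, dim))
        for chunk in _chunks(len(self.mesh.cells), chunk_size):
            u, grad = self.interpolate_velocity(U, chunk)
            speed = np.linalg.norm(u, axis=2).mean(axis=1)          # (nc,)
            h = h_min[chunk]
            tau = 1.0 / np.sqrt((2 * speed / h) ** 2 + (12 * nu / h ** 2) ** 2)
            pe = speed * h / (2 * nu)
            tau = np.where(pe > 1.0, tau, 0.0)                      # only where needed
            if not tau.any():
                continue
            dphi = self._cell_dphi(chunk)
            dpsi = self.dphi1[None] * self.inv_h[chunk][:, None, None, :]
            wdet = self.wq[None, :] * self.detJ[chunk][:, None] * tau[:, None]
            udga = np.einsum("cqe,cqae->cqa", u, dphi, optimize=True)  # (u·∇)φ
            sdiag = np.einsum("cq,cqa,cqb->cab", wdet, udga, udga, optimize=True)
            conn = self.cell_q2[chunk]
            connp = self.mesh.cells[chunk]
            rows = np.repeat(conn, nb, axis=1).ravel()
            cols = np.tile(conn, (1, nb)).ravel()
            rows_all.append(rows)
            cols_all.append(cols)
            v_diag.append(sdiag.ravel())
            rp = np.repeat(conn, nb1, axis=1).ravel()
            cp = np.tile(connp, (1, nb)).ravel()
            rows_p.append(rp)
            cols_p.append(cp)
            for d in range(dim):
                sp_d = np.einsum("cq,cqa,cqb->cab", wdet, udga, dpsi[:, :, :, d],
                                 optimize=True)
                v_p[d].append(sp_d.ravel())
            # residual: (u·∇)u + ∇p  (pressure here is kinematic-scaled upstream)
            conv = np.einsum("cqde,cqe->cqd", grad, u, optimize=True)
            gradp = np.einsum("cqbd,cb->cqd", dpsi, P[connp], optimize=True)
            r = np.einsum("cq,cqa,cqd->cad", wdet, udga, conv + gradp, optimize=True)
            np.add.at(R, conn.ravel(), r.reshape(-1, dim))
        shape = (self.n_q2, self.n_q2)
        if rows_all:
            rows = np.concatenate(rows_all)
            cols = np.concatenate(cols_all)
            S_diag = sp.coo_matrix((np.concatenate(v_diag), (rows, cols)), shape).tocsr()
            rp = np.concatenate(rows_p)
            cp = np.concatenate(cols_p)
            S_p = [
                sp.coo_matrix((np.concatenate(v_p[d]), (rp, cp)),
                              (self.n_q2, self.n_p)).tocsr()
                for d in range(dim)
            ]
        else:
            S_diag = sp.csr_matrix(shape)
            S_p = [sp.csr_matrix((self.n_q2, self.n_p)) for _ in range(dim)]
        return S_diag, S_p, R

    # -- facet operations ----------------------------------------------
    def facet_detJ(self, facet_ids: np.ndarray) -> np.ndarray:
        m = self.mesh
        sizes = m.cell_sizes[m.facet_cell[facet_ids]]
        axis = m.facet_face[facet_ids] // 2
        det = np.ones(len(facet_ids))
        for d in range(self.dim):
            det = det * np.where(axis == d, 1.0, sizes[:, d] / 2.0)
        return det

    def facet_load(self, tag: str, normal_traction) -> np.ndarray:
        """RHS vector from prescribed normal pseudo-traction −p_bc n on a tag.

        ``normal_traction`` is the scalar p_bc (Pa-equivalent in whatever
        scaling the caller uses); contributes −p_bc ∫ φ_a n ds per component.
        """
        m = self.mesh
        ids = m.facets_with_tag(tag)
        out = np.zeros((self.n_q2, self.dim))
        if len(ids) == 0:
            return out
        conn = self.facet_q2(ids)
        det = self.facet_detJ(ids)
        normals = m.facet_normals()[ids]
        w = np.einsum("q,qa->a", self.fwq, self.fphi2)   # ∫ φ_a over ref facet
        contrib = -normal_traction * det[:, None] * w[None, :]  # (nf, nbf)
        for d in range(self.dim):
            vals = contrib * normals[:, d][:, None]
            np.add.at(out[:, d], conn.ravel(), vals.ravel())
        return out

    def facet_flux(self, U: np.ndarray, tag: str) -> float:
        """∫ u·n ds over a tagged boundary (signed, outward)."""
        m = self.mesh
        ids = m.facets_with_tag(tag)
        if len(ids) == 0:
            raise KeyError(f"no facets with tag {tag!r}")
        conn = self.facet_q2(ids)
        det = self.facet_detJ(ids)
        normals = m.facet_normals()[ids]
        un = np.einsum("fad,fd->fa", U[conn], normals, optimize=True)
        vals = np.einsum("qa,fa->fq", self.fphi2, un, optimize=True)
        return float(np.einsum("q,fq,f->", self.fwq, vals, det, optimize=True))

    def inlet_bernoulli(self, U: np.ndarray, rho: float):
        """Dynamic-head terms of a total-pressure inlet.

        With traction −(p₀ − ½ρ|u|²)n on the inlet plane (outward normal
        −x, tangential velocity constrained to zero so |u| = |u_x|), the
        state-dependent part contributes +½ρ∫u_x²φ_a ds to the x-momentum
        residual and +ρ∫u_x φ_a φ_b ds to its Jacobian block.
        """
        m = self.mesh
        ids = m.facets_with_tag("inlet")
        conn = self.facet_q2(ids)
        det = self.facet_detJ(ids)
        uq = np.einsum("qa,fad->fqd", self.fphi2, U[conn], optimize=True)
        u2 = np.einsum("fqd,fqd->fq", uq, uq)
        r_loc = 0.5 * rho * np.einsum(
            "q,fq,qa,f->fa", self.fwq, u2, self.fphi2, det, optimize=True)
        R = np.zeros(self.n_q2)
        np.add.at(R, conn.ravel(), r_loc.ravel())
        nbf = conn.shape[1]
        rows = np.repeat(conn, nbf, axis=1).ravel()
        cols = np.tile(conn, (1, nbf)).ravel()
        Jb = []
        for e in range(self.dim):
            j_loc = rho * np.einsum(
                "q,fq,qa,qb,f->fab", self.fwq, uq[:, :, e], self.fphi2,
                self.fphi2, det, optimize=True)
            Jb.append(sp.coo_matrix((j_loc.ravel(), (rows, cols)),
                                    (self.n_q2, self.n_q2)).tocsr())
        return Jb, R

    def facet_velocity_gradient(self, U: np.ndarray, facet_ids: np.ndarray):
        """∇u (f, dim, dim) evaluated at each facet's center."""
        m = self.mesh
        out = np.empty((len(facet_ids), self.dim, self.dim))
        for face in range(2 * self.dim):
            sel = np.flatnonzero(m.facet_face[facet_ids] == face)
            if len(sel) == 0:
                continue
            fids = facet_ids[sel]
            cells = m.facet_cell[fids]
            dphi_ref = self.face_center_dphi[face]      # (nb2, dim)
            dphi = dphi_ref[None] * self.inv_h[cells][:, None, :]
            Uc = U[self.cell_q2[cells]]                 # (f, nb, dim)
            out[sel] = np.einsum("fae,fad->fde", dphi, Uc, optimize=True)
        return out


def _tensor_basis_at(dim: int, point: np.ndarray):
    """Q2 tensor basis at a single reference point; returns (pt, phi, dphi)."""
    n1, d1 = _shape_q2_1d(np.asarray(point))
    k = 3
    bidx = np.stack(
        [g.ravel(order="F") for g in np.meshgrid(*([np.arange(k)] * dim), indexing="ij")],
        axis=1,
    )
    nb = len(bidx)
    phi = np.ones((1, nb))
    dphi = np.ones((1, nb, dim))
    for d in range(dim):
        nd = n1[d, bidx[:, d]]
        dd = d1[d, bidx[:, d]]
        phi[0] *= nd
        for e in range(dim):
            dphi[0, :, e] *= dd if e == d else nd
    return point, phi, dphi


def _chunks(n: int, size: int):
    for start in range(0, n, size):
        yield np.arange(start, min(start + size, n))


def get_space(mesh: TaggedMesh) -> Q2Q1Space:
    """Per-mesh cached Taylor–Hood space."""
    space = getattr(mesh, "_q2q1_space", None)
    if space is None:
        space = Q2Q1Space(mesh)
        mesh._q2q1_space = space
    return space
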