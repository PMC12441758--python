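<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<meta name="viewport" content="width=device-width, initial-scale=1">
<title>{{ title }}</title>
<style>
  html, body { margin: 0; height: 100%; overflow: hidden; background: {{ background }}; }
  #tooltip {
    position: fixed; display: none; pointer-events: none; z-index: 10;
    background: rgba(20, 20, 30, 0.92); color: #f0f0f0; padding: 6px 9px;
    border-radius: 4px; font: 12px/1.5 monospace; white-space: pre;
  }
  #hud {
    position: fixed; left: 10px; top: 10px; color: #9f9faf;
    font: 12px monospace; z-index: 9; user-select: none;
  }
</style>
<script src="{{ scripts[0] }}"></script>
<script src="{{ scripts[1] }}"></script>
</head>
<body>
<div id="hud">{{ title }} &mdash; {{ point_count }} points &mdash; drag to orbit, scroll to zoom</div>
<div id="tooltip"></div>
<script type="application/json" id="scene-data">{{ data_json }}</script>
<script>
"use strict";
const points = JSON.parse(document.getElementById("scene-data").textContent);
const scene = new THREE.Scene();
scene.background = new THREE.Color("{{ background }}");
const camera = new THREE.PerspectiveCamera(60, window.innerWidth / window.innerHeight, 0.1, 5000);
camera.position.set({{ camera_distance }}, {{ camera_distance }} * 0.4, {{ camera_distance }});
const renderer = new THREE.WebGLRenderer({ antialias: true });
renderer.setSize(window.innerWidth, window.innerHeight);
document.body.appendChild(renderer.domElement);
const controls = new THREE.OrbitControls(camera, renderer.domElement);
controls.enableDamping = true;

scene.add(new THREE.AmbientLight(0xffffff, 0.55));
const keyLight = new THREE.DirectionalLight(0xffffff, 0.8);
keyLight.position.set(1, 2, 1.5);
scene.add(keyLight);

// Level of detail: the last two arguments are the width/height segment
// counts; reduce them (e.g. 32 -> 16) for very large point clouds.
const sphereGeometry = new THREE.SphereGeometry(1.0, {{ seg_w }}, {{ seg_h }});
const materials = new Map();
const meshes = [];
for (const p of points) {
  if (!materials.has(p.color)) {
    materials.set(p.color, new THREE.MeshLambertMaterial({
      color: p.color, transparent: {{ 'true' if opacity != '1.0' else 'false' }}, opacity: {{ opacity }}
    }));
  }
  const mesh = new THREE.Mesh(sphereGeometry, materials.get(p.color));
  mesh.position.set(p.position[0], p.position[1], p.position[2]);
  mesh.scale.setScalar(p.radius);
  mesh.userData = p;
  scene.add(mesh);
  meshes.push(mesh);
}

const raycaster = new THREE.Raycaster();
const mouse = new THREE.Vector2();
const tooltip = document.getElementById("tooltip");
let hovered = null;
window.addEventListener("mousemove", (event) => {
  mouse.x = (event.clientX / window.innerWidth) * 2 - 1;
  mouse.y = -(event.clientY / window.innerHeight) * 2 + 1;
  raycaster.setFromCamera(mouse, camera);
  const hits = raycaster.intersectObjects(meshes);
  if (hits.length > 0) {
    hovered = hits[0].object.userData;
    const lines = [hovered.display_name];
    for (const pair of hovered.hover_fields) lines.push(pair[0] + ": " + pair[1]);
    tooltip.textContent = lines.join("\n");
    tooltip.style.left = (event.clientX + 12) + "px";
    tooltip.style.top = (event.clientY + 12) + "px";
    tooltip.style.display = "block";
    document.body.style.cursor = hovered.hyperlink ? "pointer" : "default";
  } else {
    hovered = null;
    tooltip.style.display = "none";
    document.body.style.cursor = "default";
  }
});
window.addEventListener("click", () => {
  if (hovered && hovered.hyperlink) window.open(hovered.hyperlink, "_blank");
});
window.addEventListener("resize", () => {
  camera.aspect = window.innerWidth / window.innerHeight;
  camera.updateProjectionMatrix();
  renderer.setSize(window.innerWidth, window.innerHeight);
});
{% if cull %}
// Frustum culling: skip projecting spheres outside the camera's view
// volume to reduce per-frame load on large clouds.
const frustum = new THREE.Frustum();
const projScreenMatrix = new THREE.Matrix4();
function applyCulling() {
  projScreenMatrix.multiplyMatrices(camera.projectionMatrix, camera.matrixWorldInverse);
  frustum.setFromProjectionMatrix
    ? frustum.setFromProjectionMatrix(projScreenMatrix)
    : frustum.setFromMatrix(projScreenMatrix);
  for (const mesh of meshes) {
    mesh.visible = frustum.intersectsObject(mesh);
  }
}
{% endif %}
function animate() {
  requestAnimationFrame(animate);
  controls.update();
{% if cull %}
  applyCulling();
{% endif %}
  renderer.render(scene, camera);
}
animate();
</script>
</body>
</html>
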