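seed,target_name,relation
GPi,Subthalamic nucleus,afferent
GPi,Substantia nigra pars compacta,afferent
GPi,Ventral tegmental area,afferent
GPi,Neostriatum,afferent
GPi,Thalamus,efferent
GPi,Lateral habenula,efferent
GPi,Substantia nigra,efferent
GPi,Pedunculopontine nucleus,efferent
GPi,Cerebral cortex,efferent
GPi,Neostriatum,efferent
STN,Primary motor cortex,afferent
STN,Supplementary motor area,afferent
STN,Frontal eye field,afferent
STN,Somatosensory cortex,afferent
STN,Anterior cingulate,afferent
STN,Globus Pallidus externus,afferent
STN,Substantia nigra pars compacta,afferent
STN,Ventral tegmental area,afferent
STN,Dorsal raphe nucleus,afferent
STN,Pedunculopontine nucleus,afferent
STN,Centro-median/parafascicularis complex,afferent
STN,Globus Pallidus internus,efferent
STN,Globus Pallidus externus,efferent
STN,Substantia nigra pars compacta,efferent
STN,Substantia nigra pars reticulata,efferent
STN,Ventral thalamic nuclei,efferent
STN,Parafascicularis thalamic nucleus,efferent
STN,Substantia innominata,efferent
STN,Ventral pallidum,efferent
STN,Pedunculopontine nucleus,efferent
STN,Ipsilateral cortex,efferent
STN,Neostriatum,efferent
STN,Spinal cord,efferent
NAcc,Orbitofrontal cortex,afferent
NAcc,Anterior cingulate,afferent
NAcc,Subgenual cortex,afferent
NAcc,Pregenual cortex,afferent
NAcc,Hippocampus,afferent
NAcc,Parahippocampal cortex,afferent
NAcc,Amygdala,afferent
NAcc,Substantia nigra pars compacta,afferent
NAcc,Ventral tegmental area,afferent
NAcc,Ventral pallidum,efferent
NAcc,Substantia nigra pars compacta,efferent
NAcc,Substantia nigra pars reticulate,efferent
NAcc,Ventral tegmental area,efferent
NAcc,Hippocampus,efferent
NAcc,Caudate,efferent
NAcc,Putamen,efferent
NAcc,Medio-dorsal thalamus,efferent
NAcc,Cingulate gyrus,efferent
NAcc,Substantia innominata,efferent
NAcc,Lateral preoptic area,efferent
NAcc,Lateral hypothalamic area,efferent
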