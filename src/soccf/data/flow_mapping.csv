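flow_id,name,selector
0,Unspecified,urban
0.1,"Unspecified, used",urban
0.2,"Unspecified, natural",forest_min_asoc
1,Forest,forest_all
1.1,"Forest, natural",forest_all
1.1.1,"Forest, primary",forest_all
1.1.2,"Forest, secondary",forest_all
1.2,"Forest, used",forest_all
1.2.1,"Forest, extensive",forest_all
1.2.2,"Forest, intensive",forest_all
3,Shrub land,grassland
4,Grassland,grassland
4.1,Grassland,grassland
4.1.1,"Grassland, natural",grassland
4.1.2,"Grassland, for livestock grazing",grassland
4.2,Pasture/meadow,grassland
4.2.1,"Pasture/meadow, extensive",grassland
4.2.2,"Pasture/meadow, intensive",grassland
5,Agriculture,cropland_all
5.1,Arable,annual_all
5.1.1,"Arable, fallow",annual_all
5.1.2,"Arable, non-irrigated",annual_rainfed
5.1.2.1,"Arable, non-irrigated, extensive",annual_rainfed
5.1.2.2,"Arable, non-irrigated, intensive",annual_rainfed
5.1.3,"Arable, irrigated",annual_irrigated
5.1.3.1,"Arable, irrigated, extensive",annual_irrigated
5.1.3.2,"Arable, irrigated, intensive",annual_irrigated
5.1.4,"Arable, flooded crops",rice_irrigated
5.1.5,"Arable, greenhouse",annual_all
5.1.6,Field margins/hedgerows,annual_all
5.2,Permanent crops,permanent_all
5.2.1,"Permanent crops, non-irrigated",permanent_rainfed
5.2.1.1,"Permanent crops, non-irrigated, extensive",permanent_rainfed
5.2.1.2,"Permanent crops, non-irrigated, intensive",permanent_rainfed
5.2.2,"Permanent crops, irrigated",permanent_irrigated
5.2.2.1,"Permanent crops, irrigated, extensive",permanent_irrigated
5.2.2.2,"Permanent crops, irrigated, intensive",permanent_irrigated
6,"Agriculture, mosaic",cropland_all
7,Artificial areas,urban
7.1,Urban,urban
7.1.1,Urban/industrial fallow,urban
7.1.2,"Urban, continuously built",urban
7.1.3,"Urban, discontinuously built",urban
7.1.4,"Urban, green areas",urban
7.2,Industrial area,urban
7.3,Mineral extraction site,urban
7.4,Dump site,urban
7.5,Construction site,urban
7.6,Traffic area,urban
7.6.1,"Traffic area, road network",urban
7.6.2,"Traffic area, rail network",urban
7.6.3,"Traffic area, rail/road embankment",urban
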