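gene	c0	c1	c2	c3	c4	k0	k1	k2	k3	k4
g001	7.754277	7.966384	8.332224	7.722247	8.450667	6.572499	7.185274	6.792995	7.190722	7.032061
g002	7.630401	8.392266	8.444923	8.032674	7.975763	6.956282	6.733331	7.300423	6.851539	6.986001
g003	7.987932	8.037331	7.844826	8.593632	8.176761	7.285344	7.003936	6.794866	6.903494	6.834502
g004	8.397873	8.306147	8.324181	8.066004	8.202848	7.395902	6.839339	6.747701	7.08074	7.336833
g005	7.567811	7.94189	7.814685	7.475607	8.22525	6.992959	7.021457	6.774048	7.136592	6.838025
g006	7.610235	7.412456	7.390362	7.913132	7.535619	7.059758	6.993077	6.90962	6.895931	7.129089
g007	7.7502	7.785591	7.826451	8.098029	7.981332	7.090018	6.867404	6.674853	7.223404	7.227384
g008	7.723759	7.892871	7.952222	7.964545	7.986892	6.887121	7.375335	6.691156	7.213492	7.122372
g009	8.305229	8.772012	8.588824	7.367942	7.115608	7.379266	6.52875	6.99424	7.389869	6.236817
g010	6.655181	8.183154	8.044555	7.857409	8.040781	6.445044	6.023931	6.892523	6.373335	5.940101
g011	7.224479	6.972744	7.180463	6.560839	6.707879	6.556511	6.606408	7.086744	6.652427	7.158063
g012	7.078415	7.4674	6.678549	7.204925	6.979346	6.996762	6.665376	6.893789	7.171527	6.980964
g013	7.020233	6.92743	7.288207	6.99464	6.450725	6.827243	6.508543	6.188365	6.867671	7.332888
g014	7.024532	6.389539	6.510245	7.58863	7.082065	7.02499	6.972166	7.019992	7.419317	7.287682
g015	7.049969	6.758414	7.118401	6.841491	7.253395	6.705554	6.968119	6.998295	6.693139	7.398904
g016	7.508339	6.838635	7.268621	7.13181	6.090271	7.087159	6.978647	7.028966	6.625161	6.906246
g017	6.937991	7.413289	7.116333	6.998068	7.531866	6.806852	6.864533	6.368026	7.545827	7.335452
g018	7.164965	7.120352	7.019819	7.038772	6.954658	6.963367	7.009771	7.272017	7.099983	6.989482
g019	6.85171	6.837478	7.410198	7.129682	7.017289	6.911398	6.716147	6.982887	7.223605	6.899534
g020	6.945684	6.947168	7.026195	6.619238	6.943735	6.795782	7.211434	6.815811	7.137926	7.364372
g021	6.925396	6.856885	7.045542	6.999517	6.763619	7.109652	7.47949	6.938595	6.951736	6.751412
g022	7.167952	6.343654	6.417367	7.673553	6.523415	7.569173	7.802346	7.136497	7.291278	8.027567
g023	6.953956	6.861209	6.68328	7.009761	7.346189	7.22459	6.779506	6.799802	6.882	7.068404
g024	6.973071	7.028128	7.038921	6.960812	6.994731	7.027097	6.988986	7.066043	7.245389	7.077645
g025	7.023834	6.279947	7.165676	6.168675	6.398275	7.364972	7.301596	6.935969	6.269744	6.841416
g026	6.864994	7.126673	7.44908	7.043149	6.844989	6.767168	6.988842	6.964834	6.770954	7.023144
g027	6.779034	7.213516	7.204021	7.208264	6.908986	7.098784	6.974644	6.925351	6.934887	6.750465
g028	6.721354	7.153292	6.963094	7.041767	7.193317	6.665529	6.848673	7.033837	7.075669	6.92723
g029	7.33609	7.068707	6.603756	6.696049	7.263036	7.151469	6.37984	7.440111	7.195292	7.438684
g030	6.88622	6.912313	6.665967	7.752286	6.947972	7.470758	6.808056	7.048584	6.504387	6.886467
g031	7.417276	6.469052	7.454803	7.143045	6.557191	6.787239	6.80528	6.978996	6.772586	6.649092
g032	6.919341	6.728065	6.658515	6.987242	7.233798	6.595001	7.000929	6.827882	6.741238	7.226002
g033	6.913942	7.24884	6.870483	7.064191	6.962252	6.874771	7.097602	6.97426	7.100182	6.992146
g034	6.62466	6.964717	7.01796	7.331317	6.686725	6.986405	6.404788	7.225205	6.626158	6.375585
g035	6.95713	7.800467	5.896368	6.21231	6.461902	6.182294	7.274689	6.415502	6.477655	7.422287
g036	6.807739	7.110133	6.752805	6.691539	6.53292	7.473633	6.918501	7.062075	6.992099	7.040707
g037	7.009519	7.365581	6.80096	6.701618	6.806126	6.744293	7.143105	7.15717	6.815829	6.733617
g038	6.899028	7.395902	6.197574	7.149874	6.693849	7.29608	6.693232	6.918773	6.571326	6.721881
g039	7.206389	7.122207	6.940181	6.870408	6.71796	6.941374	6.995398	6.987482	6.986032	6.832932
g040	6.981651	6.989293	7.357312	7.516834	6.962072	6.787836	6.982009	6.831771	6.794446	6.983762
g041	6.732007	7.15569	6.973307	7.06422	6.953008	6.81319	6.756498	6.939051	6.85904	7.060082
g042	6.998194	6.444977	7.027346	6.452899	6.748838	6.880076	6.154504	7.037281	7.061513	6.935619
g043	6.87526	6.890168	6.712918	6.920714	6.837544	7.026954	6.646009	7.069259	7.042103	6.958383
g044	6.914841	7.107095	6.677246	7.089279	7.047123	7.054945	7.074322	6.873263	6.949693	7.123521
g045	7.083076	7.039878	6.707866	7.103766	7.225608	7.19478	7.045118	6.699501	7.18183	6.971592
g046	6.567413	7.064432	6.745118	6.778551	6.891541	7.217375	6.936655	7.046289	7.298575	7.272281
g047	6.979488	6.952068	6.749768	6.862178	7.084417	7.078537	7.021878	7.197428	6.846716	6.988871
g048	7.157503	7.12582	7.230672	7.085515	6.933358	7.078013	6.78405	6.646875	7.125071	6.988123
g049	7.231141	5.727654	6.726362	6.550431	6.352308	5.309957	6.749026	7.672493	7.285542	6.549615
g050	6.994582	7.275626	5.994657	6.954644	7.197833	7.248431	7.619405	7.413383	7.113835	7.10998
g051	7.097096	6.933456	6.995041	7.111815	7.241517	6.980349	6.994028	7.024489	7.165729	6.99626
g052	7.468424	6.691834	6.940693	6.936826	7.250734	7.333224	6.518797	6.708265	7.107387	6.790012
g053	6.68843	7.212528	7.101093	7.10093	6.902698	7.210576	6.950891	7.224389	6.813425	6.825198
g054	7.054414	6.813271	7.179582	7.069149	6.75461	7.019373	6.906606	7.243492	6.831824	6.883237
g055	7.245611	7.453935	7.405353	7.01282	7.044379	7.31095	6.974767	6.802019	7.0237	7.091557
g056	6.790509	6.584067	6.637	7.168126	6.808391	6.964288	7.053705	7.156431	6.915384	7.126004
g057	6.648814	6.857281	6.595803	7.446554	6.989314	6.708296	6.860967	6.912514	7.2764	6.37042
g058	6.63011	6.865159	7.903074	7.340815	6.960254	7.253914	7.733726	6.916642	6.869329	7.432205
g059	7.112543	7.152888	6.884258	7.438215	7.38934	7.128888	7.155839	6.538315	7.145231	6.955794
g060	7.136251	7.2143	6.892831	6.46917	7.115517	6.767197	6.896315	6.810177	6.892742	6.274785
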